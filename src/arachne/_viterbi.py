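"""Numba kernel for local Viterbi alignment of a nucleotide profile HMM.

The dynamic programme is local in both sequence and model: a path may enter
any match state from an unscored begin (score 0) and leave any match state
for an unscored end, so flanking sequence costs nothing.  Scores are
log2-odds against the background null; insert states emit with log-odds 0
(background emission), so only transitions penalise inserts.  Bases encoded
4 (N) carry emission log-odds 0 in every state.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1.0e30


@njit(cache=True)
def viterbi_local(obs, em, tMM, tMI, tMD, tIM, tII, tDM, tDD):
    """Best local alignment of ``obs`` (int8 codes 0..4) to the profile.

    ``em`` is the (M, 5) match emission log2-odds table (column 4 = 0 for N).
    Transition arrays are log2 probabilities indexed by source match column.

    Returns ``(score, i_from, i_to, k_from, k_to)`` with inclusive 0-based
    sequence positions and model columns of the best-scoring path.
    """
    L = obs.shape[0]
    M = em.shape[0]
    VM = np.full((L, M), NEG)
    VI = np.full((L, M), NEG)
    VD = np.full((L, M), NEG)
    pM = np.zeros((L, M), dtype=np.int8)  # 0 begin, 1 M, 2 I, 3 D (all diagonal)
    pI = np.zeros((L, M), dtype=np.int8)  # 1 from M, 2 from I (same column)
    pD = np.zeros((L, M), dtype=np.int8)  # 1 from M, 3 from D (same row)

    best = 0.0
    bi = -1
    bk = -1
    for i in range(L):
        x = obs[i]
        for k in range(M):
            # match
            v = 0.0  # free begin
            p = np.int8(0)
            if k > 0 and i > 0:
                c = VM[i - 1, k - 1] + tMM[k - 1]
                if c > v:
                    v = c
                    p = np.int8(1)
                c = VI[i - 1, k - 1] + tIM[k - 1]
                if c > v:
                    v = c
                    p = np.int8(2)
                c = VD[i - 1, k - 1] + tDM[k - 1]
                if c > v:
                    v = c
                    p = np.int8(3)
            vm = v + em[k, x]
            VM[i, k] = vm
            pM[i, k] = p
            if vm > best:
                best = vm
                bi = i
                bk = k
            # delete (no sequence consumed; same row, previous column)
            if k > 0:
                c1 = VM[i, k - 1] + tMD[k - 1]
                c2 = VD[i, k - 1] + tDD[k - 1]
                if c1 >= c2:
                    VD[i, k] = c1
                    pD[i, k] = np.int8(1)
                else:
                    VD[i, k] = c2
                    pD[i, k] = np.int8(3)
            # insert (emits with log-odds 0)
            if i > 0:
                c1 = VM[i - 1, k] + tMI[k]
                c2 = VI[i - 1, k] + tII[k]
                if c1 >= c2:
                    VI[i, k] = c1
                    pI[i, k] = np.int8(1)
                else:
                    VI[i, k] = c2
                    pI[i, k] = np.int8(2)

    if bi < 0:
        return 0.0, -1, -1, -1, -1

    # traceback from the best match cell to the begin entry
    i = bi
    k = bk
    state = 1  # 1 M, 2 I, 3 D
    i_from = bi
    k_from = bk
    while True:
        if state == 1:
            i_from = i
            k_from = k
            p = pM[i, k]
            if p == 0:
                break
            state = int(p)
            i -= 1
            k -= 1
        elif state == 2:
            p = pI[i, k]
            state = int(p)
            i -= 1
        else:  # D
            p = pD[i, k]
            state = int(p)
            k -= 1
    return best, i_from, bi, k_from, bk
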