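"""Independent reference implementations used only to check the package.

Each oracle recomputes a quantity by a different route than the library:
exhaustive path enumeration for Viterbi, transitive-closure components for
overlap resolution, a dense GLS solve for ancestral states, a full
state-space breadth-first search for inversion distances, and a plain
codon walk for the stop-codon scan.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"


# ---------------------------------------------------------------------------
# exhaustive local-alignment enumeration
# ---------------------------------------------------------------------------


def brute_force_viterbi(profile, seq: str) -> float:
    """Max score over all local alignments by explicit path enumeration.

    A path starts at any match column/sequence position, moves through
    match/insert/delete states with the profile's log2-odds scores, and ends
    at any match state.  Scores below 0 collapse to 0 (the empty alignment),
    mirroring the free begin/end of the scanner.  Exponential: use only for
    M <= 6 and len(seq) <= 12.
    """
    em, (tMM, tMI, tMD, tIM, tII, tDM, tDD) = profile._log2_tables()
    M = profile.M
    L = len(seq)
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    obs = [code.get(c, 4) for c in seq]
    best = 0.0

    def extend(state: str, i: int, k: int, score: float) -> None:
        nonlocal best
        if state == "M":
            best = max(best, score)
        if k + 1 < M and i + 1 < L and state in ("M", "I", "D"):
            t = {"M": tMM, "I": tIM, "D": tDM}[state][k]
            extend("M", i + 1, k + 1, score + t + em[k + 1, obs[i + 1]])
        if i + 1 < L and state in ("M", "I"):
            t = {"M": tMI, "I": tII}[state][k]
            extend("I", i + 1, k, score + t)
        if k + 1 < M and state in ("M", "D"):
            t = {"M": tMD, "D": tDD}[state][k]
            extend("D", i, k + 1, score + t)

    for i in range(L):
        for k in range(M):
            extend("M", i, k, em[k, obs[i]])
    return best


# ---------------------------------------------------------------------------
# overlap components by transitive closure
# ---------------------------------------------------------------------------


def component_best_calls(hits) -> list:
    """Overlap resolution oracle: boolean closure + argmin per component."""
    n = len(hits)
    adj = np.eye(n, dtype=bool)
    for i in range(n):
        for j in range(n):
            a, b = hits[i].interval, hits[j].interval
            if (
                a.scaffold == b.scaffold
                and a.strand == b.strand
                and a.start < b.end
                and b.start < a.end
            ):
                adj[i, j] = True
    closure = adj.copy()
    for _ in range(n):
        closure = closure | (closure @ closure)
    seen: set[int] = set()
    winners = []
    for i in range(n):
        if i in seen:
            continue
        comp = [j for j in range(n) if closure[i, j]]
        seen.update(comp)
        winners.append(
            min(
                (hits[j] for j in comp),
                key=lambda h: (h.evalue, -h.bit_score, h.interval.start, h.class_label),
            )
        )
    return winners


# ---------------------------------------------------------------------------
# dense GLS ancestral-state solve
# ---------------------------------------------------------------------------


def gls_ancestral(tree, tip_values: dict[str, float]) -> dict[int, float]:
    """Ancestral BM states from the full phylogenetic covariance system."""

    def path_to_root(u: int) -> list[int]:
        path = []
        while u != tree.root:
            path.append(u)
            u = tree.parent[u]
        return path

    def shared_length(a: int, b: int) -> float:
        pa = set(path_to_root(a))
        return sum(tree.blen[u] for u in path_to_root(b) if u in pa)

    tips = tree.tips
    y = np.array([tip_values[tree.labels[t]] for t in tips])
    n = len(tips)
    C = np.empty((n, n))
    for i, a in enumerate(tips):
        for j, b in enumerate(tips):
            C[i, j] = shared_length(a, b) if i != j else sum(
                tree.blen[u] for u in path_to_root(a)
            )
    Cinv = np.linalg.inv(C)
    ones = np.ones(n)
    mu = (ones @ Cinv @ y) / (ones @ Cinv @ ones)
    out = {}
    for node in tree.internal_nodes:
        if node == tree.root:
            out[node] = float(mu)
            continue
        c = np.array([shared_length(node, t) for t in tips])
        out[node] = float(mu + c @ Cinv @ (y - mu))
    return out


def random_tree(rng: np.random.Generator, n_tips: int):
    """Random rooted bifurcating tree with branch lengths in [0.1, 2]."""
    from arachne.ancestral import Phylogeny

    def bl() -> float:
        return float(rng.uniform(0.1, 2.0))

    subtrees = [f"t{i}:{bl():.4f}" for i in range(n_tips)]
    while len(subtrees) > 2:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        b = subtrees.pop(j)
        a = subtrees.pop(i)
        subtrees.append(f"({a},{b}):{bl():.4f}")
    newick = f"({subtrees[0]},{subtrees[1]});"
    return Phylogeny.from_newick(newick)


# ---------------------------------------------------------------------------
# inversion distances by full-space BFS
# ---------------------------------------------------------------------------


def all_inversion_distances(n: int) -> dict[tuple, int]:
    """Distance from identity for every signed permutation of 1..n."""
    ident = tuple(range(1, n + 1))
    dist = {ident: 0}
    frontier = [ident]
    while frontier:
        nxt = []
        for s in frontier:
            for i in range(n):
                for j in range(i, n):
                    t = s[:i] + tuple(-g for g in reversed(s[i : j + 1])) + s[j + 1 :]
                    if t not in dist:
                        dist[t] = dist[s] + 1
                        nxt.append(t)
        frontier = nxt
    return dist


# ---------------------------------------------------------------------------
# codon walk
# ---------------------------------------------------------------------------


def first_stop_upstream(seq: str, region_start: int, frame: int) -> str:
    """Plain scan for the first in-frame stop codon; 500 bp before it."""
    stops = {"TAA", "TAG", "TGA"}
    positions = [p for p in range(frame, len(seq) - 2, 3) if p >= region_start]
    for p in positions:
        if seq[p : p + 3] in stops:
            return seq[max(0, p - 500) : p]
    raise ValueError("no stop found")
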