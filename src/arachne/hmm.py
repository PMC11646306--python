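"""Nucleotide profile HMMs: training, E-value calibration and genome scanning.

A profile is built from a trimmed reference alignment of a spidroin
terminal-domain class (or a hox gene's homeobox): match columns are the
alignment columns with gap fraction < 0.5, emissions and transitions are
Laplace-smoothed counts, and the background is the training-set base
composition.  Scanning is local Viterbi in log2-odds ("bit") units on both
strands, with significance from a seeded Gumbel calibration on random
background sequences — the usual extreme-value treatment of local alignment
score maxima.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from arachne._viterbi import viterbi_local
from arachne.seqio import GenomicInterval, MultipleAlignment, SequenceRecord, revcomp

__all__ = [
    "SPIDROIN_CLASSES",
    "HOX_GENES",
    "NucleotideProfile",
    "HmmHit",
    "trim_conserved",
    "build_profile",
    "viterbi_score",
    "calibrate",
    "evalue",
    "scan",
    "profile_to_json",
    "profile_from_json",
    "hits_to_frame",
    "parse_nhmmer_tblout",
]

SPIDROIN_CLASSES = [
    "AcSp", "AgSp", "CrSp", "CySp", "Flag",
    "MaSp", "MiSp", "Pflag", "PySp", "unclassified",
]
HOX_GENES = ["lab", "pb", "Hox3", "Dfd", "Scr", "ftz", "Antp", "Ubx", "AbdA", "AbdB"]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def encode(seq: str) -> np.ndarray:
    out = np.empty(len(seq), dtype=np.int8)
    for i, c in enumerate(seq):
        out[i] = _CODE.get(c, 4)
    return out


@dataclass
class NucleotideProfile:
    """Position-specific scoring model with Gumbel calibration parameters."""

    model_id: str
    class_label: str
    terminus: str  # NTD, CTD or none
    M: int
    match_emissions: np.ndarray  # (M, 4)
    insert_emissions: np.ndarray  # (4,) shared background-like
    tMM: np.ndarray
    tMI: np.ndarray
    tMD: np.ndarray
    tIM: np.ndarray
    tII: np.ndarray
    tDM: np.ndarray
    tDD: np.ndarray
    background: np.ndarray  # (4,)
    n_train: int
    gumbel_mu: float = math.nan
    gumbel_lambda: float = math.nan
    calib_seq_len: int = 0

    @property
    def calibrated(self) -> bool:
        return math.isfinite(self.gumbel_mu) and math.isfinite(self.gumbel_lambda)

    def consensus(self) -> str:
        return "".join("ACGT"[j] for j in np.argmax(self.match_emissions, axis=1))

    def _log2_tables(self):
        em = np.zeros((self.M, 5))
        em[:, :4] = np.log2(self.match_emissions / self.background[None, :])
        logs = tuple(
            np.log2(t) for t in
            (self.tMM, self.tMI, self.tMD, self.tIM, self.tII, self.tDM, self.tDD)
        )
        return em, logs


@dataclass
class HmmHit:
    """One genomic match of a profile."""

    model_id: str
    class_label: str
    terminus: str
    interval: GenomicInterval
    bit_score: float
    bias_score: float
    evalue: float
    model_cov: float
    ali_from: int  # 1-based inclusive model coordinates
    ali_to: int


def trim_conserved(
    aln: MultipleAlignment, min_identity: float = 0.6, window: int = 10
) -> MultipleAlignment:
    """Crop alignment ends until a conserved core is reached.

    Leading/trailing columns are removed until the first/last window of
    ``window`` columns has mean majority-residue conservation >=
    ``min_identity``.  Conservation of a column is the excess majority
    fraction (top count - 1) / (rows - 1): 1 for an invariant column, 0
    when every row differs, and ~0.25 in expectation for unrelated random
    DNA regardless of row count.  Interior columns are never touched.
    """
    n_col = aln.n_columns
    R = aln.n_rows

    def majority_freq(j: int) -> float:
        col = aln.column(j)
        residues = [c for c in col if c != "-"]
        if not residues:
            return 0.0
        top = max(residues.count(b) for b in set(residues))
        return (top - 1) / (R - 1)

    freqs = [majority_freq(j) for j in range(n_col)]

    lo = None
    for s in range(0, n_col - window + 1):
        if float(np.mean(freqs[s : s + window])) >= min_identity:
            lo = s
            break
    hi = None
    for e in range(n_col, window - 1, -1):
        if float(np.mean(freqs[e - window : e])) >= min_identity:
            hi = e
            break
    if lo is None or hi is None or hi - lo < window:
        raise ValueError("no conserved core")
    return aln.slice_columns(lo, hi)


def build_profile(
    aln: MultipleAlignment,
    model_id: str,
    class_label: str = "",
    terminus: str = "none",
) -> NucleotideProfile:
    """Estimate a profile from a (trimmed) alignment.

    Match columns: gap fraction < 0.5.  Emissions: +1 Laplace pseudocount per
    base, (count + 1) / (total + 4).  Transitions: counts of observed
    per-row state paths with +1 pseudocounts.  Background: training-set base
    frequencies.  Calibration parameters stay NaN until :func:`calibrate`.
    """
    R = aln.n_rows
    n_col = aln.n_columns
    is_match = []
    for j in range(n_col):
        col = aln.column(j)
        gap_frac = col.count("-") / R
        is_match.append(gap_frac < 0.5)
    match_cols = [j for j, m in enumerate(is_match) if m]
    M = len(match_cols)
    if M < 5:
        raise ValueError(f"fewer than 5 match columns ({M}) in {model_id}")

    counts = np.zeros((M, 4))
    bg_counts = np.zeros(4)
    for row in aln.rows:
        for c in row:
            if c in "ACGT":
                bg_counts[_CODE[c]] += 1
    for k, j in enumerate(match_cols):
        for row in aln.rows:
            c = row[j]
            if c in "ACGT":
                counts[k, _CODE[c]] += 1
    match_emissions = (counts + 1.0) / (counts.sum(axis=1, keepdims=True) + 4.0)
    background = (
        (bg_counts + 1.0) / (bg_counts.sum() + 4.0)
        if bg_counts.sum() > 0
        else np.full(4, 0.25)
    )

    # transition counts from per-row state paths (+1 pseudocounts)
    cMM = np.ones(M); cMI = np.ones(M); cMD = np.ones(M)
    cIM = np.ones(M); cII = np.ones(M)
    cDM = np.ones(M); cDD = np.ones(M)
    col_kind = []  # (kind, match_index) kind in {M, I}
    k = -1
    for j in range(n_col):
        if is_match[j]:
            k += 1
            col_kind.append(("M", k))
        else:
            col_kind.append(("I", k))
    for row in aln.rows:
        prev = None  # (state, k)
        for j, (kind, kk) in enumerate(col_kind):
            c = row[j]
            if kind == "M":
                state = ("M", kk) if c != "-" else ("D", kk)
            else:
                if c == "-":
                    continue
                state = ("I", max(kk, 0))
            if prev is not None:
                ps, pk = prev
                s, sk = state
                if ps == "M" and s == "M":
                    cMM[pk] += 1
                elif ps == "M" and s == "I":
                    cMI[pk] += 1
                elif ps == "M" and s == "D":
                    cMD[pk] += 1
                elif ps == "I" and s == "M":
                    cIM[pk] += 1
                elif ps == "I" and s == "I":
                    cII[pk] += 1
                elif ps == "D" and s == "M":
                    cDM[pk] += 1
                elif ps == "D" and s == "D":
                    cDD[pk] += 1
                # D->I / I->D are not modelled; such adjacencies are skipped
            prev = state

    m_tot = cMM + cMI + cMD
    i_tot = cIM + cII
    d_tot = cDM + cDD
    return NucleotideProfile(
        model_id=model_id,
        class_label=class_label,
        terminus=terminus,
        M=M,
        match_emissions=match_emissions,
        insert_emissions=background.copy(),
        tMM=cMM / m_tot, tMI=cMI / m_tot, tMD=cMD / m_tot,
        tIM=cIM / i_tot, tII=cII / i_tot,
        tDM=cDM / d_tot, tDD=cDD / d_tot,
        background=background,
        n_train=R,
    )


def viterbi_score(profile: NucleotideProfile, seq: str):
    """Best local alignment of ``seq`` to the profile.

    Returns ``(bit_score, (seq_start, seq_end), (ali_from, ali_to))`` with a
    0-based half-open sequence span and 1-based inclusive model columns.
    A score <= 0 means no positive-scoring alignment exists; the spans are
    then empty.
    """
    if len(seq) < 1:
        raise ValueError("empty sequence")
    em, (lMM, lMI, lMD, lIM, lII, lDM, lDD) = profile._log2_tables()
    obs = encode(seq)
    score, i0, i1, k0, k1 = viterbi_local(obs, em, lMM, lMI, lMD, lIM, lII, lDM, lDD)
    if score <= 0 or i0 < 0:
        return float(score), (0, 0), (0, 0)
    return float(score), (int(i0), int(i1) + 1), (int(k0) + 1, int(k1) + 1)


def calibrate(
    profile: NucleotideProfile,
    n_seqs: int = 200,
    seq_len: int = 1000,
    seed: int = 0,
) -> NucleotideProfile:
    """Fit Gumbel (mu, lambda) to max local scores on random background.

    Scores ``n_seqs`` i.i.d. sequences of length ``seq_len`` drawn from the
    profile background and fits a Gumbel law by maximum likelihood.  The
    E-value of a later hit of score S in a search of total length L (both
    strands counted) is ``(L / seq_len) * exp(-lambda * (S - mu))`` — the
    database-size scaling treats the search as L/seq_len independent
    calibration-sized windows.
    """
    rng = np.random.default_rng(seed)
    em, logs = profile._log2_tables()
    scores = np.empty(n_seqs)
    for r in range(n_seqs):
        obs = rng.choice(4, size=seq_len, p=profile.background).astype(np.int8)
        scores[r] = viterbi_local(obs, em, *logs)[0]
    loc, scale = stats.gumbel_r.fit(scores)
    if scale <= 0 or not math.isfinite(scale):
        raise ValueError("degenerate Gumbel fit; increase n_seqs")
    profile.gumbel_mu = float(loc)
    profile.gumbel_lambda = float(1.0 / scale)
    profile.calib_seq_len = int(seq_len)
    return profile


def evalue(profile: NucleotideProfile, score: float, db_len: int) -> float:
    """Expected number of hits >= ``score`` in ``db_len`` scanned bases."""
    if not profile.calibrated:
        raise ValueError(f"profile {profile.model_id} is not calibrated")
    exponent = -profile.gumbel_lambda * (score - profile.gumbel_mu)
    if exponent > 700.0:
        return math.inf
    return (db_len / profile.calib_seq_len) * math.exp(exponent)


def _span_bias(span: str, background: np.ndarray) -> float:
    """Compositional bias of the aligned span, in bits.

    The span re-scored against a null re-estimated from its own base
    frequencies loses sum_x n_x log2(q_x / bg_x) bits relative to the
    background null; that difference (n * KL(q || bg), always >= 0) is the
    part of the bit score attributable to composition alone.
    """
    counts = np.zeros(4)
    for c in span:
        j = _CODE.get(c, 4)
        if j < 4:
            counts[j] += 1
    n = counts.sum()
    if n == 0:
        return 0.0
    q = counts / n
    nz = counts > 0
    return float(np.sum(counts[nz] * np.log2(q[nz] / background[nz])))


def _scan_oriented(obs: np.ndarray, em, logs, window: int, overlap: int,
                   stop_score: float, max_iter: int = 50):
    """Candidate hits (score, i_from, i_to, k_from, k_to) on one orientation.

    The sequence is scanned in overlapping windows; within a window the best
    hit is extracted and its span masked to N (emission log-odds 0) until the
    best remaining score drops below ``stop_score``.  Window overlap exceeds
    any plausible alignment length, so every hit is fully contained in at
    least one window; duplicates from the overlap are resolved by the caller.
    """
    L = obs.shape[0]
    out = []
    step = max(window - overlap, 1)
    starts = list(range(0, max(L - overlap, 1), step))
    for w0 in starts:
        w1 = min(w0 + window, L)
        sub = obs[w0:w1].copy()
        for _ in range(max_iter):
            score, i0, i1, k0, k1 = viterbi_local(sub, em, *logs)
            if i0 < 0 or score < stop_score:
                break
            out.append((float(score), w0 + int(i0), w0 + int(i1), int(k0), int(k1)))
            sub[i0 : i1 + 1] = 4
        if w1 >= L:
            break
    return out


def scan(
    profile: NucleotideProfile,
    genome: list[SequenceRecord],
    evalue_report: float = 10.0,
) -> list[HmmHit]:
    """Scan both strands of a genome, reporting hits with E <= ``evalue_report``.

    Hit coordinates are forward-strand with a strand flag.  Overlapping
    candidates (window-overlap duplicates, masked re-finds) are reduced to
    the locally best non-overlapping set per strand.
    """
    if not profile.calibrated:
        raise ValueError(f"profile {profile.model_id} is not calibrated")
    em, logs = profile._log2_tables()
    db_len = 2 * sum(len(r) for r in genome)
    if db_len == 0:
        return []
    # score below which E > evalue_report: S < mu - log(E*calib/db)/lambda
    stop_score = profile.gumbel_mu - (
        math.log(evalue_report * profile.calib_seq_len / db_len)
        / profile.gumbel_lambda
    )
    stop_score = max(stop_score, 1.0)
    window = max(5000, 40 * profile.M)
    overlap = min(2000, max(600, 4 * profile.M))

    hits: list[HmmHit] = []
    for rec in genome:
        L = len(rec)
        for strand in ("+", "-"):
            seq = rec.residues if strand == "+" else revcomp(rec.residues)
            obs = encode(seq)
            cands = _scan_oriented(obs, em, logs, window, overlap, stop_score)
            cands.sort(key=lambda c: (-c[0], c[1]))
            kept: list[tuple] = []
            for c in cands:
                if any(not (c[2] < k[1] or k[2] < c[1]) for k in kept):
                    continue
                kept.append(c)
            for score, i0, i1, k0, k1 in kept:
                if strand == "+":
                    start, end = i0, i1 + 1
                else:
                    start, end = L - 1 - i1, L - i0
                span = seq[i0 : i1 + 1]
                hits.append(
                    HmmHit(
                        model_id=profile.model_id,
                        class_label=profile.class_label,
                        terminus=profile.terminus,
                        interval=GenomicInterval(rec.id, start, end, strand),
                        bit_score=score,
                        bias_score=_span_bias(span, profile.background),
                        evalue=evalue(profile, score, db_len),
                        model_cov=(k1 - k0 + 1) / profile.M,
                        ali_from=k0 + 1,
                        ali_to=k1 + 1,
                    )
                )
    hits = [h for h in hits if h.evalue <= evalue_report]
    hits.sort(key=lambda h: (h.interval.scaffold, h.interval.start, h.interval.strand))
    return hits


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

_ARRAY_FIELDS = [
    "match_emissions", "insert_emissions", "tMM", "tMI", "tMD",
    "tIM", "tII", "tDM", "tDD", "background",
]


def profile_to_json(profile: NucleotideProfile, path: str | Path) -> None:
    d = asdict(profile)
    for f in _ARRAY_FIELDS:
        d[f] = np.asarray(d[f]).tolist()
    with open(path, "w") as fh:
        json.dump(d, fh, indent=1)


def profile_from_json(path: str | Path) -> NucleotideProfile:
    with open(path) as fh:
        d = json.load(fh)
    for f in _ARRAY_FIELDS:
        d[f] = np.asarray(d[f], dtype=float)
    return NucleotideProfile(**d)


def hits_to_frame(hits: list[HmmHit]):
    """Hit table with the documented TSV columns."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "model_id": h.model_id,
                "class": h.class_label,
                "terminus": h.terminus,
                "scaffold": h.interval.scaffold,
                "start": h.interval.start,
                "end": h.interval.end,
                "strand": h.interval.strand,
                "bit_score": h.bit_score,
                "bias_score": h.bias_score,
                "evalue": h.evalue,
                "model_cov": h.model_cov,
                "ali_from": h.ali_from,
                "ali_to": h.ali_to,
            }
            for h in hits
        ],
        columns=[
            "model_id", "class", "terminus", "scaffold", "start", "end",
            "strand", "bit_score", "bias_score", "evalue", "model_cov",
            "ali_from", "ali_to",
        ],
    )


def frame_to_hits(df) -> list[HmmHit]:
    """Inverse of :func:`hits_to_frame` (e.g. after a TSV round trip)."""
    return [
        HmmHit(
            model_id=r["model_id"],
            class_label=r["class"],
            terminus=r["terminus"],
            interval=GenomicInterval(
                r["scaffold"], int(r["start"]), int(r["end"]), r["strand"]
            ),
            bit_score=float(r["bit_score"]),
            bias_score=float(r["bias_score"]),
            evalue=float(r["evalue"]),
            model_cov=float(r["model_cov"]),
            ali_from=int(r["ali_from"]),
            ali_to=int(r["ali_to"]),
        )
        for _, r in df.iterrows()
    ]


def parse_nhmmer_tblout(
    path: str | Path, class_label: str, terminus: str, model_len: int
) -> list[HmmHit]:
    """Adapter for an external nhmmer search (tabular ``--tblout`` output).

    Lets users substitute the external engine for the built-in scanner while
    keeping the same hit contract downstream.  Not used by the pipeline or
    the tests.
    """
    hits = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.split()
            ali_from, ali_to = int(f[4]), int(f[5])
            env_from, env_to = int(f[6]), int(f[7])
            strand = f[11]
            start, end = (env_from - 1, env_to) if strand == "+" else (env_to - 1, env_from)
            hits.append(
                HmmHit(
                    model_id=f[2],
                    class_label=class_label,
                    terminus=terminus,
                    interval=GenomicInterval(f[0], start, end, strand),
                    bit_score=float(f[13]),
                    bias_score=float(f[14]),
                    evalue=float(f[12]),
                    model_cov=(abs(ali_to - ali_from) + 1) / model_len,
                    ali_from=min(ali_from, ali_to),
                    ali_to=max(ali_from, ali_to),
                )
            )
    return hits
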