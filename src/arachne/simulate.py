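"""Synthetic genomes with planted spidroin genes and hox clusters.

The generator stands in for real assemblies and reference sets: it draws
per-class terminal-domain consensus sequences (mutually divergent by
construction), emits reference alignments of noisy variants to train
profiles from, and plants gene structures into i.i.d. background DNA of
configurable GC content — spidroin genes (NTD + low-complexity repeat
region + CTD on a random strand), solitary domains, discordant-class
pairs, oversized pairs, and hox clusters with configurable losses, tandem
duplications, inversions, internal gaps and scaffold-edge truncation.
Everything planted is recorded in a truth table so predictions can be
scored without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from arachne.hox import ANCESTRAL_ORDER, HoxGeneCall
from arachne.seqio import GenomicInterval, MultipleAlignment, SequenceRecord, revcomp

__all__ = [
    "SpidroinPlan",
    "HoxClusterPlan",
    "SimulationSpec",
    "TruthTable",
    "default_benchmark_spec",
    "make_reference_set",
    "simulate_genome",
    "truth_to_hox_calls",
    "evaluate_recovery",
]

BASES = np.array(list("ACGT"))
#: glycine/alanine-codon-like low-complexity motif tiled into repeat regions
REPEAT_MOTIF = "GGAGCAGGTGCA"
DOMAIN_LEN = 150
HOX_DOMAIN_LEN = 180


@dataclass(frozen=True)
class SpidroinPlan:
    spidroin_class: str
    n_copies: int = 1
    divergence: float = 0.1
    repeat_len: int | None = None  # None: span drawn uniformly in [5, 50] kbp


@dataclass(frozen=True)
class HoxClusterPlan:
    name: str = "hoxA"
    ftz_absent: bool = False  # definitional for a B cluster, not a loss event
    losses: tuple[str, ...] = ()
    tandem_duplications: tuple[str, ...] = ()
    inversions: tuple[tuple[int, int], ...] = ()  # inclusive index ranges
    internal_gap: tuple[int, int] | None = None  # (adjacency index, gap bp)
    truncate_after: int | None = None  # scaffold ends just after this gene index
    divergence: float = 0.1
    gap_bp: tuple[int, int] = (10_000, 30_000)
    ancestral: tuple[str, ...] = ANCESTRAL_ORDER


@dataclass(frozen=True)
class SimulationSpec:
    seed: int = 42
    scaffold_lengths: tuple[int, ...] = (750_000, 750_000)
    gc: float = 0.35
    spidroins: tuple[SpidroinPlan, ...] = ()
    discordant_pairs: int = 0
    oversized_pairs: int = 0
    oversized_span: int = 120_000
    solitary_ntds: int = 0
    solitary_ctds: int = 0
    hox_clusters: tuple[HoxClusterPlan, ...] = ()
    divergence: float = 0.1
    hard_mode: bool = False  # adds tandem-repeat background stress regions

    def __post_init__(self) -> None:
        if not 0.0 <= self.divergence <= 0.3:
            raise ValueError("divergence must be in [0, 0.3]")
        if any(l <= 0 for l in self.scaffold_lengths):
            raise ValueError("scaffold lengths must be positive")


def default_benchmark_spec(seed: int = 42) -> SimulationSpec:
    """The default study conditions: a ~2 Mbp genome with 24 spidroin genes
    in 6 classes at 10% divergence and two hox clusters, the B copy carrying
    one loss, one tandem duplication and one inversion."""
    return SimulationSpec(
        seed=seed,
        scaffold_lengths=(750_000, 750_000),
        gc=0.35,
        spidroins=(
            SpidroinPlan("MaSp", 6),
            SpidroinPlan("MiSp", 5),
            SpidroinPlan("AcSp", 4),
            SpidroinPlan("CySp", 3),
            SpidroinPlan("Flag", 3),
            SpidroinPlan("PySp", 3),
        ),
        hox_clusters=(
            HoxClusterPlan(name="hoxA"),
            HoxClusterPlan(
                name="hoxB",
                ftz_absent=True,
                losses=("Hox3",),
                tandem_duplications=("Dfd",),
                inversions=((4, 6),),
            ),
        ),
    )


@dataclass
class TruthTable:
    """Everything planted, with exact coordinates and expected outcomes."""

    domains: list[dict] = field(default_factory=list)
    genes: list[dict] = field(default_factory=list)
    hox_genes: list[dict] = field(default_factory=list)
    clusters: list[dict] = field(default_factory=list)

    def frames(self) -> dict[str, pd.DataFrame]:
        return {
            "domains": pd.DataFrame(self.domains),
            "genes": pd.DataFrame(self.genes),
            "hox_genes": pd.DataFrame(self.hox_genes),
            "clusters": pd.DataFrame(self.clusters),
        }

    def write(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.frames().items():
            df.to_csv(out / f"truth_{name}.tsv", sep="\t", index=False)

    @classmethod
    def read(cls, outdir) -> "TruthTable":
        from pathlib import Path

        out = Path(outdir)
        tables = {}
        for name in ("domains", "genes", "hox_genes", "clusters"):
            fp = out / f"truth_{name}.tsv"
            if fp.exists():
                df = pd.read_csv(fp, sep="\t")
                tables[name] = df.to_dict(orient="records")
            else:
                tables[name] = []
        return cls(**tables)


# ---------------------------------------------------------------------------
# reference sets
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[rng.choice(4, size=n, p=p)])


def _identity(a: str, b: str) -> float:
    return sum(x == y for x, y in zip(a, b)) / len(a)


def mutate(seq: str, divergence: float, rng: np.random.Generator) -> str:
    """Substitute each base with probability ``divergence`` (to a different base)."""
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(len(seq)) < divergence
    for i in np.nonzero(hit)[0]:
        choices = [b for b in b"ACGT" if bytes([b]) != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return arr.tobytes().decode()


def _sample_consensi(
    keys: list, length_of, rng: np.random.Generator, max_identity: float = 0.60
) -> dict:
    """Mutually divergent consensus sequences via rejection sampling."""
    consensus: dict = {}
    for key in keys:
        n = length_of(key)
        for _ in range(1000):
            cand = _random_seq(rng, n)
            if all(
                _identity(cand, other) <= max_identity
                for other in consensus.values()
                if len(other) == n
            ):
                consensus[key] = cand
                break
        else:
            raise RuntimeError("rejection sampling of divergent consensi failed")
    return consensus


def _variant_alignment(
    consensus: str,
    n_seqs: int,
    divergence: float,
    rng: np.random.Generator,
    indel_p: float = 0.02,
    prefix: str = "seq",
) -> MultipleAlignment:
    """Aligned noisy variants: i.i.d. substitutions plus geometric indels.

    Divergence 0 means exact copies: indels are suppressed along with
    substitutions so the rows reproduce the consensus verbatim.
    """
    if divergence == 0:
        indel_p = 0.0
    n = len(consensus)
    per_row: list[tuple[list[str], list[str]]] = []  # (chars per column, inserts after)
    for _ in range(n_seqs):
        mutated = mutate(consensus, divergence, rng)
        chars = list(mutated)
        inserts = [""] * n
        j = 0
        while j < n:
            if rng.random() < indel_p:
                dlen = min(int(rng.geometric(0.5)), n - j)
                for k in range(j, j + dlen):
                    chars[k] = "-"
                j += dlen
                continue
            if rng.random() < indel_p:
                inserts[j] = _random_seq(rng, int(rng.geometric(0.5)))
            j += 1
        per_row.append((chars, inserts))

    rows = []
    max_ins = [max(len(r[1][j]) for r in per_row) for j in range(n)]
    for chars, inserts in per_row:
        parts = []
        for j in range(n):
            parts.append(chars[j])
            parts.append(inserts[j].ljust(max_ins[j], "-"))
        rows.append("".join(parts))
    ids = [f"{prefix}_{i + 1}" for i in range(n_seqs)]
    return MultipleAlignment(ids, rows)


def make_reference_set(
    classes: list[str],
    n_seqs_per_class: int = 20,
    domain_len: int = DOMAIN_LEN,
    divergence: float = 0.1,
    seed: int = 0,
    termini: tuple[str, ...] = ("NTD", "CTD"),
) -> tuple[dict, dict]:
    """Per-class, per-terminus reference alignments plus a consensus store.

    Returns ``(alignments, consensus)``, both keyed by ``(class, terminus)``.
    Class consensi are pairwise <= 60% identical by rejection sampling, so
    near-miss cross-class hits occur but the best class is decidable.
    """
    rng = np.random.default_rng(seed)
    keys = [(c, t) for c in classes for t in termini]
    consensus = _sample_consensi(keys, lambda k: domain_len, rng)
    alignments = {
        key: _variant_alignment(
            cons, n_seqs_per_class, divergence, rng, prefix=f"{key[0]}_{key[1]}"
        )
        for key, cons in consensus.items()
    }
    return alignments, consensus


# ---------------------------------------------------------------------------
# genome simulation
# ---------------------------------------------------------------------------


def _repeat_region(length: int, rng: np.random.Generator) -> str:
    reps = REPEAT_MOTIF * (length // len(REPEAT_MOTIF) + 1)
    return mutate(reps[:length], 0.02, rng)


@dataclass
class _Cassette:
    kind: str  # gene, discordant, oversized, solitary_ntd, solitary_ctd
    ntd_class: str | None
    ctd_class: str | None
    seq: str
    strand: str
    span: int
    expected: str  # detected-as-gene, discordant, filtered, unpaired


def _gene_cassette(
    kind: str,
    ntd_class: str | None,
    ctd_class: str | None,
    span: int | None,
    expected: str,
    consensus: dict,
    divergence: float,
    rng: np.random.Generator,
) -> _Cassette:
    parts = []
    if ntd_class:
        parts.append(mutate(consensus[(ntd_class, "NTD")], divergence, rng))
    if ntd_class and ctd_class:
        dlen = len(parts[0]) + len(consensus[(ctd_class, "CTD")])
        parts.append(_repeat_region(span - dlen, rng))
    if ctd_class:
        parts.append(mutate(consensus[(ctd_class, "CTD")], divergence, rng))
    fwd = "".join(parts)
    strand = "+" if rng.random() < 0.5 else "-"
    seq = fwd if strand == "+" else revcomp(fwd)
    return _Cassette(kind, ntd_class, ctd_class, seq, strand, len(fwd), expected)


def _place(
    cassettes: list, lengths: list[int], rng: np.random.Generator, margin: int = 2000
):
    """Assign cassettes to scaffolds and draw non-overlapping positions.

    Greedy capacity packing, then per-scaffold random order with slack split
    into random gaps — placement is exact and can never collide.
    """
    loads: list[list] = [[] for _ in lengths]
    used = [2 * margin] * len(lengths)
    for cas in sorted(cassettes, key=lambda c: -len(c.seq)):
        order = sorted(
            range(len(lengths)), key=lambda i: -(lengths[i] - used[i])
        )
        best = order[0]
        if lengths[best] - used[best] < len(cas.seq) + margin:
            raise ValueError("requested features exceed scaffold capacity")
        loads[best].append(cas)
        used[best] += len(cas.seq) + margin
    placements: list[list[tuple[int, object]]] = []
    for i, group in enumerate(loads):
        if not group:
            placements.append([])
            continue
        group = [group[j] for j in rng.permutation(len(group))]
        slack = lengths[i] - sum(len(c.seq) for c in group)
        w = rng.random(len(group) + 1)
        gaps = np.floor(w / w.sum() * slack).astype(int)
        pos, out = 0, []
        for g, cas in zip(gaps, group):
            pos += int(g)
            out.append((pos, cas))
            pos += len(cas.seq)
        placements.append(out)
    return placements


def _build_cluster_order(plan: HoxClusterPlan) -> list[tuple[str, int]]:
    order = [(g, 1) for g in plan.ancestral]
    drop = set(plan.losses) | ({"ftz"} if plan.ftz_absent else set())
    order = [(g, s) for g, s in order if g not in drop]
    for gene in plan.tandem_duplications:
        idx = [i for i, (g, _) in enumerate(order) if g == gene]
        if not idx:
            raise ValueError(f"cannot tandem-duplicate absent gene {gene!r}")
        order.insert(idx[0] + 1, order[idx[0]])
    for i, j in plan.inversions:
        if not (0 <= i <= j < len(order)):
            raise ValueError(f"inversion range ({i}, {j}) out of bounds")
        order[i : j + 1] = [(g, -s) for g, s in reversed(order[i : j + 1])]
    return order


def simulate_genome(
    spec: SimulationSpec, consensus: dict, hox_consensus: dict | None = None
) -> tuple[list[SequenceRecord], TruthTable]:
    """Generate scaffolds and a truth table from a simulation spec.

    ``consensus`` maps (class, terminus) to the planted domain consensus;
    ``hox_consensus`` maps (gene, "none") or gene name to the homeobox
    consensus (required when the spec plants hox clusters).  Same seed,
    same spec: byte-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    truth = TruthTable()
    classes = sorted({p.spidroin_class for p in spec.spidroins})

    cassettes: list[_Cassette] = []
    for plan in spec.spidroins:
        for _ in range(plan.n_copies):
            span = (
                plan.repeat_len + 2 * DOMAIN_LEN
                if plan.repeat_len is not None
                else int(rng.integers(5_000, 50_001))
            )
            cassettes.append(
                _gene_cassette(
                    "gene", plan.spidroin_class, plan.spidroin_class, span,
                    "detected-as-gene", consensus, plan.divergence, rng,
                )
            )
    pool = classes if len(classes) >= 2 else ["MaSp", "MiSp"]
    for k in range(spec.discordant_pairs):
        a = pool[k % len(pool)]
        b = pool[(k + 1) % len(pool)]
        span = int(rng.integers(5_000, 30_001))
        cassettes.append(
            _gene_cassette(
                "discordant", a, b, span, "discordant",
                consensus, spec.divergence, rng,
            )
        )
    for k in range(spec.oversized_pairs):
        a = pool[k % len(pool)]
        cassettes.append(
            _gene_cassette(
                "oversized", a, a, spec.oversized_span, "filtered",
                consensus, spec.divergence, rng,
            )
        )
    for k in range(spec.solitary_ntds):
        cassettes.append(
            _gene_cassette(
                "solitary_ntd", pool[k % len(pool)], None, None, "unpaired",
                consensus, spec.divergence, rng,
            )
        )
    for k in range(spec.solitary_ctds):
        cassettes.append(
            _gene_cassette(
                "solitary_ctd", None, pool[k % len(pool)], None, "unpaired",
                consensus, spec.divergence, rng,
            )
        )

    lengths = list(spec.scaffold_lengths)
    placements = _place(cassettes, lengths, rng)

    records: list[SequenceRecord] = []
    gene_no = 0
    for i, length in enumerate(lengths):
        name = f"scaffold_{i + 1}"
        arr = np.array(list(_random_seq(rng, length, spec.gc)))
        if spec.hard_mode:
            for _ in range(max(1, length // 200_000)):
                rl = int(rng.integers(2_000, 10_000))
                rs = int(rng.integers(0, length - rl))
                arr[rs : rs + rl] = list(_repeat_region(rl, rng))
        for pos, cas in placements[i]:
            arr[pos : pos + len(cas.seq)] = list(cas.seq)
            gene_no += 1
            gid = f"planted_{gene_no:03d}"
            span = len(cas.seq)
            if cas.ntd_class and cas.ctd_class:
                if cas.strand == "+":
                    ntd_iv = (pos, pos + DOMAIN_LEN)
                    ctd_iv = (pos + span - DOMAIN_LEN, pos + span)
                else:
                    ntd_iv = (pos + span - DOMAIN_LEN, pos + span)
                    ctd_iv = (pos, pos + DOMAIN_LEN)
                for term, cls, iv in (
                    ("NTD", cas.ntd_class, ntd_iv),
                    ("CTD", cas.ctd_class, ctd_iv),
                ):
                    truth.domains.append(
                        dict(gene_id=gid, scaffold=name, start=iv[0], end=iv[1],
                             strand=cas.strand, terminus=term, spidroin_class=cls,
                             expected=cas.expected)
                    )
                expected_class = (
                    cas.ntd_class if cas.ntd_class == cas.ctd_class else "discordant"
                )
                truth.genes.append(
                    dict(gene_id=gid, scaffold=name, start=pos, end=pos + span,
                         strand=cas.strand, span_bp=span,
                         spidroin_class=expected_class, expected=cas.expected)
                )
            else:
                term = "NTD" if cas.ntd_class else "CTD"
                cls = cas.ntd_class or cas.ctd_class
                truth.domains.append(
                    dict(gene_id=gid, scaffold=name, start=pos, end=pos + span,
                         strand=cas.strand, terminus=term, spidroin_class=cls,
                         expected="unpaired")
                )
        records.append(SequenceRecord(name, "".join(arr)))

    # hox clusters, one scaffold each
    for plan in spec.hox_clusters:
        if hox_consensus is None:
            raise ValueError("hox clusters requested but no hox consensus given")
        order = _build_cluster_order(plan)
        margin = 20_000
        gaps = [int(rng.integers(*plan.gap_bp)) for _ in range(len(order) - 1)]
        if plan.internal_gap is not None:
            adj, bp = plan.internal_gap
            gaps[adj] = bp
        starts = [margin]
        for k, gap in enumerate(gaps):
            starts.append(starts[-1] + HOX_DOMAIN_LEN + gap)
        total = starts[-1] + HOX_DOMAIN_LEN + margin

        kept = order
        truncated = False
        if plan.truncate_after is not None:
            kept = order[: plan.truncate_after + 1]
            truncated = True
            total = starts[plan.truncate_after] + HOX_DOMAIN_LEN + 2_000

        name = f"{plan.name}_scaffold"
        arr = np.array(list(_random_seq(rng, total, spec.gc)))
        signed_order = []
        for k, (gene, sign) in enumerate(kept):
            key = (gene, "none") if (gene, "none") in hox_consensus else gene
            var = mutate(hox_consensus[key], plan.divergence, rng)
            strand = "+" if sign > 0 else "-"
            if strand == "-":
                var = revcomp(var)
            s = starts[k]
            arr[s : s + HOX_DOMAIN_LEN] = list(var)
            signed_order.append(gene if sign > 0 else f"-{gene}")
            truth.hox_genes.append(
                dict(cluster=plan.name, scaffold=name, gene=gene, start=s,
                     end=s + HOX_DOMAIN_LEN, strand=strand)
            )
        truth.clusters.append(
            dict(cluster=plan.name, scaffold=name,
                 signed_order=",".join(signed_order),
                 expected_label="B" if plan.ftz_absent else "A",
                 n_losses=len(plan.losses),
                 n_tandem_duplications=len(plan.tandem_duplications),
                 n_inversions=len(plan.inversions),
                 truncated=truncated)
        )
        records.append(SequenceRecord(name, "".join(arr)))

    return records, truth


def truth_to_hox_calls(truth: TruthTable) -> list[HoxGeneCall]:
    """Turn planted hox genes into calls (for stages downstream of the scan)."""
    return [
        HoxGeneCall(
            gene=row["gene"],
            interval=GenomicInterval(
                row["scaffold"], row["start"], row["end"], row["strand"]
            ),
            evalue=1e-30,
            bit_score=100.0,
        )
        for row in truth.hox_genes
    ]


# ---------------------------------------------------------------------------
# recovery metrics
# ---------------------------------------------------------------------------


def _match_loci(
    preds: list[tuple[str, int, int, str]],
    truths: list[tuple[str, int, int, str]],
    tol: int,
) -> tuple[int, list[tuple[int, int]]]:
    """Greedy one-to-one matching on (scaffold, start, end) within ``tol``.

    Returns (n_matched, list of (pred_index, truth_index)).  Labels (4th
    element) are not compared here; callers score them on matched pairs.
    """
    used: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for pi, (scaf, start, end, _) in enumerate(preds):
        for ti, (tscaf, tstart, tend, _) in enumerate(truths):
            if ti in used or tscaf != scaf:
                continue
            if abs(start - tstart) <= tol and abs(end - tend) <= tol:
                used.add(ti)
                pairs.append((pi, ti))
                break
    return len(pairs), pairs


def _prf(tp: int, n_pred: int, n_truth: int) -> dict:
    precision = tp / n_pred if n_pred else 0.0
    recall = tp / n_truth if n_truth else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "n_pred": n_pred,
        "n_truth": n_truth,
        "undefined_precision": n_pred == 0,
    }


def evaluate_recovery(
    truth: TruthTable,
    genes=None,
    domain_calls=None,
    hox_calls=None,
    cluster_reports: dict | None = None,
    locus_tol_bp: int = 100,
) -> dict:
    """Precision/recall/F1 of predictions against the planted truth.

    A prediction matches a truth feature iff same scaffold and both
    endpoints within ``locus_tol_bp``.  Class/gene label metrics are scored
    on locus-matched pairs.  ``cluster_reports`` maps planted cluster name
    to a RearrangementReport for exact event-count comparison.
    """
    out: dict = {}

    if domain_calls is not None:
        preds = [
            (c.interval.scaffold, c.interval.start, c.interval.end, c.class_label)
            for c in domain_calls
        ]
        truths = [
            (d["scaffold"], d["start"], d["end"], d["spidroin_class"])
            for d in truth.domains
        ]
        tp, _ = _match_loci(preds, truths, locus_tol_bp)
        out["domains"] = _prf(tp, len(preds), len(truths))

    if genes is not None:
        preds = [
            (g.interval.scaffold, g.interval.start, g.interval.end, g.final_class)
            for g in genes
        ]
        expected = [t for t in truth.genes if t["expected"] != "filtered"]
        truths = [
            (t["scaffold"], t["start"], t["end"], t["spidroin_class"])
            for t in expected
        ]
        tp, pairs = _match_loci(preds, truths, locus_tol_bp)
        out["genes"] = _prf(tp, len(preds), len(truths))
        class_tp = sum(1 for pi, ti in pairs if preds[pi][3] == truths[ti][3])
        out["classes"] = _prf(class_tp, len(preds), len(truths))

    if hox_calls is not None:
        preds = [
            (c.interval.scaffold, c.interval.start, c.interval.end, c.gene)
            for c in hox_calls
        ]
        truths = [
            (h["scaffold"], h["start"], h["end"], h["gene"])
            for h in truth.hox_genes
        ]
        tp, pairs = _match_loci(preds, truths, locus_tol_bp)
        gene_tp = sum(1 for pi, ti in pairs if preds[pi][3] == truths[ti][3])
        out["hox"] = _prf(gene_tp, len(preds), len(truths))

    if cluster_reports is not None:
        n = exact = 0
        for cl in truth.clusters:
            rep = cluster_reports.get(cl["cluster"])
            if rep is None:
                continue
            n += 1
            if (
                rep.losses == cl["n_losses"]
                and rep.tandem_duplications == cl["n_tandem_duplications"]
                and rep.inversions == cl["n_inversions"]
                and rep.unexplained == 0
            ):
                exact += 1
        out["cluster_events"] = {
            "exact_match_rate": exact / n if n else 0.0,
            "n": n,
        }
    return out
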