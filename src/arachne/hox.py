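"""Hox cluster identification, A/B labelling and rearrangement counting.

Arachnopulmonate genomes carry two copies of the 10-gene hox cluster
(lab, pb, Hox3, Dfd, Scr, ftz, Antp, Ubx, AbdA, AbdB); the copy that lost
ftz is Cluster B, the other Cluster A.  Homeobox profile hits are filtered
at E < 1e-20, merged into loci, partitioned into clusters along each
scaffold, labelled, and each non-fragmented cluster is compared with the
ancestral gene order by counting losses, tandem duplications and the exact
minimum number of signed inversions (breadth-first search over reversal
moves — exact at this alphabet size).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from arachne.hmm import HmmHit, HOX_GENES
from arachne.seqio import GenomicInterval

__all__ = [
    "ANCESTRAL_ORDER",
    "HoxGeneCall",
    "HoxCluster",
    "RearrangementReport",
    "call_hox_genes",
    "partition_clusters",
    "label_clusters",
    "flag_fragmented",
    "inversion_distance",
    "count_rearrangements",
    "orthology_table",
]

logger = logging.getLogger(__name__)

#: canonical arthropod hox gene order assumed ancestral (config-overridable)
ANCESTRAL_ORDER = tuple(HOX_GENES)

DEFAULT_HOX_EVALUE_MAX = 1e-20
DEFAULT_MERGE_BP = 1000
DEFAULT_GAP_THRESHOLD_BP = 5_000_000
DEFAULT_EDGE_BP = 10_000


@dataclass
class HoxGeneCall:
    gene: str
    interval: GenomicInterval
    evalue: float
    bit_score: float

    @property
    def sign(self) -> int:
        return 1 if self.interval.strand == "+" else -1


@dataclass
class HoxCluster:
    cluster_id: str
    scaffold: str
    calls: list[HoxGeneCall]
    label: str = "unlabelled"  # A, B or unlabelled
    separated_copies: list[HoxGeneCall] = field(default_factory=list)
    fragmented: bool = False

    @property
    def members(self) -> list[str]:
        """Ordered signed gene names, e.g. ['lab', '-pb', ...]."""
        return [
            c.gene if c.sign > 0 else f"-{c.gene}" for c in self.calls
        ]

    @property
    def genes(self) -> list[str]:
        return [c.gene for c in self.calls]

    @property
    def start(self) -> int:
        return min(c.interval.start for c in self.calls)

    @property
    def end(self) -> int:
        return max(c.interval.end for c in self.calls)


@dataclass
class RearrangementReport:
    losses: int
    tandem_duplications: int
    inversions: int
    unexplained: int = 0

    @property
    def total(self) -> int:
        return self.losses + self.tandem_duplications + self.inversions + self.unexplained


def call_hox_genes(
    hits: list[HmmHit],
    evalue_max: float = DEFAULT_HOX_EVALUE_MAX,
    merge_bp: int = DEFAULT_MERGE_BP,
) -> list[HoxGeneCall]:
    """Merge per-profile homeobox hits into gene loci.

    Hits below the E-value threshold (from all 10 profiles together) that
    overlap or lie within ``merge_bp`` of each other on a scaffold are one
    locus; the locus takes the gene of its lowest-E member.
    """
    kept = [h for h in hits if h.evalue < evalue_max]
    kept.sort(key=lambda h: (h.interval.scaffold, h.interval.start))
    calls: list[HoxGeneCall] = []
    group: list[HmmHit] = []

    def flush(group: list[HmmHit]) -> None:
        if not group:
            return
        best = min(group, key=lambda h: (h.evalue, -h.bit_score, h.class_label))
        lo = min(h.interval.start for h in group)
        hi = max(h.interval.end for h in group)
        calls.append(
            HoxGeneCall(
                gene=best.class_label,
                interval=GenomicInterval(
                    group[0].interval.scaffold, lo, hi, best.interval.strand
                ),
                evalue=best.evalue,
                bit_score=best.bit_score,
            )
        )

    end = -1
    scaf = None
    for h in kept:
        if group and h.interval.scaffold == scaf and h.interval.start <= end + merge_bp:
            group.append(h)
            end = max(end, h.interval.end)
        else:
            flush(group)
            group = [h]
            end = h.interval.end
            scaf = h.interval.scaffold
    flush(group)
    return calls


def partition_clusters(
    calls: list[HoxGeneCall],
    gap_threshold_bp: int = DEFAULT_GAP_THRESHOLD_BP,
    genome: str = "",
) -> list[HoxCluster]:
    """Partition one genome's calls into clusters along each scaffold.

    Duplicate-aware greedy walk in coordinate order: a repeated gene is
    tolerated inside a cluster only as an immediately adjacent (tandem)
    copy; any other repeat opens a new cluster.  Large gaps alone never
    split a cluster — real B clusters stretch over tens of Mbp.  Afterwards
    a singleton cluster lying more than ``gap_threshold_bp`` from a
    neighbouring cluster that already contains its gene is re-attached to
    that neighbour as a separated extra copy; scaffolds with a single hox
    gene keep their singleton clusters.
    """
    clusters: list[HoxCluster] = []
    by_scaffold: dict[str, list[HoxGeneCall]] = {}
    for c in calls:
        by_scaffold.setdefault(c.interval.scaffold, []).append(c)

    for scaf in sorted(by_scaffold):
        scalls = sorted(by_scaffold[scaf], key=lambda c: c.interval.start)
        scaf_clusters: list[HoxCluster] = []
        current: list[HoxGeneCall] = []
        seen: set[str] = set()
        for c in scalls:
            tandem_like = (
                bool(current)
                and current[-1].gene == c.gene
                and c.interval.start - current[-1].interval.end <= gap_threshold_bp
            )
            if current and c.gene in seen and not tandem_like:
                scaf_clusters.append(
                    HoxCluster(f"{genome}:{scaf}:{len(clusters) + len(scaf_clusters)}",
                               scaf, current)
                )
                current = []
                seen = set()
            current.append(c)
            seen.add(c.gene)
        if current:
            scaf_clusters.append(
                HoxCluster(f"{genome}:{scaf}:{len(clusters) + len(scaf_clusters)}",
                           scaf, current)
            )
        _absorb_separated(scaf_clusters, gap_threshold_bp)
        clusters.extend(scaf_clusters)
    return clusters


def _absorb_separated(scaf_clusters: list[HoxCluster], gap_threshold_bp: int) -> None:
    """Fold far-away singleton duplicates into their neighbour cluster."""
    changed = True
    while changed:
        changed = False
        for i, cl in enumerate(scaf_clusters):
            if len(cl.calls) != 1:
                continue
            call = cl.calls[0]
            for j in (i - 1, i + 1):
                if not (0 <= j < len(scaf_clusters)):
                    continue
                nb = scaf_clusters[j]
                if len(nb.calls) < 2 or call.gene not in nb.genes:
                    continue
                gap = max(nb.start, call.interval.start) - min(
                    nb.end, call.interval.end
                )
                if gap > gap_threshold_bp:
                    nb.separated_copies.append(call)
                    scaf_clusters.pop(i)
                    changed = True
                    break
            if changed:
                break


def label_clusters(clusters: list[HoxCluster]) -> list[HoxCluster]:
    """Assign A/B labels for one genome's clusters.

    The multi-gene cluster carrying ftz is A and its ftz-less partner B.  A
    genome with a single multi-gene cluster (mite-like) gets A.  Ambiguous
    configurations (both or neither with ftz) stay unlabelled with a logged
    warning.
    """
    multi = [c for c in clusters if len(c.calls) >= 2]
    if len(multi) > 2:
        logger.warning(
            "%d multi-gene hox clusters found; labelling the two largest",
            len(multi),
        )
        multi = sorted(multi, key=lambda c: -len(c.calls))[:2]
    if len(multi) == 1:
        multi[0].label = "A"
        return clusters
    if len(multi) == 2:
        with_ftz = [c for c in multi if "ftz" in c.genes]
        if len(with_ftz) == 1:
            with_ftz[0].label = "A"
            other = multi[0] if multi[1] is with_ftz[0] else multi[1]
            other.label = "B"
        else:
            logger.warning(
                "ftz present in %d of 2 clusters; cannot assign A/B labels",
                len(with_ftz),
            )
    return clusters


def flag_fragmented(
    cluster: HoxCluster,
    scaffold_length: int,
    expected_genes: tuple[str, ...] = ANCESTRAL_ORDER,
    edge_bp: int = DEFAULT_EDGE_BP,
) -> bool:
    """True iff the cluster misses expected genes AND touches a scaffold end.

    ftz is not expected in a B cluster.  Fragmented clusters are excluded
    from rearrangement counting.
    """
    expected = set(expected_genes)
    if cluster.label == "B":
        expected.discard("ftz")
    missing = expected - set(cluster.genes)
    at_edge = (
        cluster.start <= edge_bp or cluster.end >= scaffold_length - edge_bp
    )
    cluster.fragmented = bool(missing) and at_edge
    return cluster.fragmented


# ---------------------------------------------------------------------------
# inversion distance
# ---------------------------------------------------------------------------


def _reversals(state: tuple[int, ...]):
    n = len(state)
    for i in range(n):
        for j in range(i, n):
            yield state[:i] + tuple(-g for g in reversed(state[i : j + 1])) + state[j + 1 :]


def inversion_distance(
    perm: tuple[int, ...], max_depth: int = 10, max_states: int = 2_000_000
) -> int:
    """Minimum number of signed reversals sorting ``perm`` to identity.

    Exact bidirectional breadth-first search over reversal moves; raises
    ``RuntimeError`` if the search exceeds ``max_depth`` or ``max_states``
    (never reached for the <= 10-gene clusters this package handles in
    practice).
    """
    n = len(perm)
    ident = tuple(range(1, n + 1))
    if perm == ident:
        return 0
    front_a = {perm}
    front_b = {ident}
    seen_a = {perm: 0}
    seen_b = {ident: 0}
    depth = 0
    while depth < max_depth:
        # expand the smaller frontier
        if len(front_a) <= len(front_b):
            front, seen, other = front_a, seen_a, seen_b
            which_a = True
        else:
            front, seen, other = front_b, seen_b, seen_a
            which_a = False
        depth += 1
        new = set()
        for s in front:
            d = seen[s]
            for t in _reversals(s):
                if t in other:
                    return d + 1 + other[t]
                if t not in seen:
                    seen[t] = d + 1
                    new.add(t)
        if which_a:
            front_a = new
        else:
            front_b = new
        if len(seen_a) + len(seen_b) > max_states:
            raise RuntimeError("inversion-distance search exceeded state budget")
        if not new:
            break
    raise RuntimeError(f"inversion distance exceeds max_depth={max_depth}")


def count_rearrangements(
    cluster: HoxCluster,
    ancestral: tuple[str, ...] = ANCESTRAL_ORDER,
) -> RearrangementReport:
    """Structural events separating a cluster from the ancestral order.

    losses: ancestral genes absent from the cluster (ftz absence in a B
    cluster is definitional, not a loss).  tandem_duplications: adjacent
    same-gene copies beyond the first.  inversions: after collapsing
    duplicates and dropping lost genes, the exact minimum number of signed
    segment reversals turning the ancestral order into the observed one.
    Non-adjacent extra copies (or an out-of-budget reversal search) are
    counted as unexplained events.
    """
    if cluster.fragmented:
        raise ValueError("refusing to count rearrangements on a fragmented cluster")
    for g in cluster.genes:
        if g not in ancestral:
            raise ValueError(f"gene {g!r} not in ancestral order")

    present = set(cluster.genes)
    lost = [g for g in ancestral if g not in present]
    if cluster.label == "B" and "ftz" in lost:
        lost.remove("ftz")
    losses = len(lost)

    # collapse adjacent same-gene runs, counting tandem duplications
    collapsed: list[tuple[str, int]] = []
    tandem = 0
    for c in cluster.calls:
        if collapsed and collapsed[-1][0] == c.gene:
            tandem += 1
            continue
        collapsed.append((c.gene, c.sign))

    unexplained = 0
    seen: set[str] = set()
    deduped: list[tuple[str, int]] = []
    for g, s in collapsed:
        if g in seen:
            unexplained += 1  # non-adjacent extra copy: not a tandem duplication
            continue
        seen.add(g)
        deduped.append((g, s))

    surviving = [g for g in ancestral if g in seen]
    rank = {g: i + 1 for i, g in enumerate(surviving)}
    perm = tuple(rank[g] * s for g, s in deduped)
    try:
        inversions = inversion_distance(perm)
    except RuntimeError:
        logger.warning("inversion search did not converge for %s", cluster.cluster_id)
        inversions = 0
        unexplained += 1
    return RearrangementReport(losses, tandem, inversions, unexplained)


def orthology_table(labelled: dict[str, list[HoxCluster]]) -> pd.DataFrame:
    """One row per (genome, gene copy) with its cluster assignment.

    ``labelled`` maps genome name to its clusters.  Copies in a labelled
    cluster inherit its A/B label (assumed orthologous within a label);
    separated copies are flagged; calls in unlabelled singleton clusters are
    reported as unplaced.
    """
    rows = []
    for genome, clusters in labelled.items():
        for cl in clusters:
            in_cluster = cl.label != "unlabelled" and len(cl.calls) >= 2
            for c in cl.calls:
                rows.append(
                    {
                        "genome": genome,
                        "gene": c.gene,
                        "scaffold": c.interval.scaffold,
                        "start": c.interval.start,
                        "cluster": cl.label if in_cluster else "unplaced",
                        "separated": False,
                    }
                )
            for c in cl.separated_copies:
                rows.append(
                    {
                        "genome": genome,
                        "gene": c.gene,
                        "scaffold": c.interval.scaffold,
                        "start": c.interval.start,
                        "cluster": cl.label if in_cluster else "unplaced",
                        "separated": True,
                    }
                )
    return pd.DataFrame(
        rows, columns=["genome", "gene", "scaffold", "start", "cluster", "separated"]
    )
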