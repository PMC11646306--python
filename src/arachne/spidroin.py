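"""Spidroin gene annotation from terminal-domain profile hits.

Spidroin (spider silk fibroin) genes consist of a conserved N-terminal
domain (NTD), a long low-complexity repeat region, and a conserved
C-terminal domain (CTD).  Hits of per-class NTD/CTD profiles are filtered
(E-value, bias, model coverage), reduced to non-overlapping best-class
calls, paired NTD-to-next-downstream-CTD on the same scaffold and strand,
capped at a 100 kbp genomic span, and classified with the unclassified
class acting as a wildcard; class disagreement between the two domains
yields a "discordant" gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median

from arachne.hmm import HmmHit
from arachne.seqio import GenomicInterval, Gff3Feature, revcomp

__all__ = [
    "CLASS_VOCAB",
    "TerminalDomainCall",
    "SpidroinGene",
    "RepertoireSummary",
    "filter_hits",
    "resolve_overlaps",
    "pair_terminals",
    "classify_gene",
    "extract_candidate_ctd",
    "summarize_repertoire",
    "genes_to_gff3",
]

#: spidroin class vocabulary; "unclassified" is a wildcard, "MesCTD" is the
#: Mesothelae-specific C-terminal domain treated as a CTD-side wildcard.
CLASS_VOCAB = {
    "AcSp", "AgSp", "CrSp", "CySp", "Flag", "MaSp", "MiSp", "Pflag",
    "PySp", "unclassified", "MesCTD",
}
_WILDCARDS = {"unclassified", "MesCTD"}

DEFAULT_EVALUE_MAX = 1e-10
DEFAULT_MIN_MODEL_COV = 0.90
DEFAULT_MAX_GENE_SPAN = 100_000
STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class TerminalDomainCall:
    interval: GenomicInterval
    terminus: str  # NTD or CTD
    class_label: str
    evalue: float
    bit_score: float
    bias_score: float
    model_cov: float


@dataclass
class SpidroinGene:
    interval: GenomicInterval  # NTD start to CTD end (forward coordinates)
    ntd: TerminalDomainCall
    ctd: TerminalDomainCall
    final_class: str

    @property
    def span_bp(self) -> int:
        return len(self.interval)


@dataclass
class RepertoireSummary:
    species: str
    counts: dict[str, int]
    gene_lengths: list[int]
    median_length_by_class: dict[str, float]
    n_unpaired_ntds: int
    n_unpaired_ctds: int

    @property
    def n_genes(self) -> int:
        return sum(self.counts.values())


def filter_hits(
    hits: list[HmmHit],
    evalue_max: float = DEFAULT_EVALUE_MAX,
    min_model_cov: float = DEFAULT_MIN_MODEL_COV,
) -> list[HmmHit]:
    """Keep hits with E-value < threshold, bit score strictly above bias
    score, and model coverage of at least ``min_model_cov``; order preserved."""
    return [
        h
        for h in hits
        if h.evalue < evalue_max
        and h.bit_score > h.bias_score
        and h.model_cov >= min_model_cov
    ]


def resolve_overlaps(hits: list[HmmHit], terminus: str) -> list[TerminalDomainCall]:
    """Reduce overlapping same-strand hits (all classes) to best-class calls.

    Hits on the same scaffold and strand sharing >= 1 bp form overlap
    components (transitively); each component yields one call for its member
    with the lowest E-value (ties: higher bit score, smaller start,
    lexicographic class).
    """
    pool = [h for h in hits if h.terminus == terminus]
    pool.sort(key=lambda h: (h.interval.scaffold, h.interval.strand, h.interval.start))
    components: list[list[HmmHit]] = []
    cur: list[HmmHit] = []
    cur_end = -1
    cur_key = None
    for h in pool:
        key = (h.interval.scaffold, h.interval.strand)
        if cur and key == cur_key and h.interval.start < cur_end:
            cur.append(h)
            cur_end = max(cur_end, h.interval.end)
        else:
            if cur:
                components.append(cur)
            cur = [h]
            cur_end = h.interval.end
            cur_key = key
    if cur:
        components.append(cur)

    calls = []
    for comp in components:
        best = min(
            comp,
            key=lambda h: (h.evalue, -h.bit_score, h.interval.start, h.class_label),
        )
        calls.append(
            TerminalDomainCall(
                interval=best.interval,
                terminus=terminus,
                class_label=best.class_label,
                evalue=best.evalue,
                bit_score=best.bit_score,
                bias_score=best.bias_score,
                model_cov=best.model_cov,
            )
        )
    calls.sort(key=lambda c: (c.interval.scaffold, c.interval.start))
    return calls


def classify_gene(ntd_class: str, ctd_class: str) -> str:
    """Combine the two domain classes into the gene's final class.

    Equal classes keep the class; a wildcard domain (unclassified, or the
    Mesothelae CTD) defers to its partner; two wildcards give
    "unclassified"; anything else is "discordant".
    """
    for label in (ntd_class, ctd_class):
        if label not in CLASS_VOCAB:
            raise ValueError(f"unknown spidroin class {label!r}")
    if ntd_class == ctd_class:
        return "unclassified" if ntd_class in _WILDCARDS else ntd_class
    if ntd_class in _WILDCARDS and ctd_class in _WILDCARDS:
        return "unclassified"
    if ntd_class in _WILDCARDS:
        return ctd_class
    if ctd_class in _WILDCARDS:
        return ntd_class
    return "discordant"


def pair_terminals(
    ntds: list[TerminalDomainCall],
    ctds: list[TerminalDomainCall],
    max_gene_span: int = DEFAULT_MAX_GENE_SPAN,
) -> tuple[list[SpidroinGene], list[TerminalDomainCall], list[TerminalDomainCall]]:
    """Pair each NTD with its nearest downstream unused CTD.

    Pairing is per scaffold and strand, walking NTDs 5'->3' in strand
    orientation; "downstream" follows the strand.  A pair spanning more than
    ``max_gene_span`` is not a gene: the NTD is reported unpaired and the
    CTD stays available to closer NTDs.  Each CTD closes at most one gene.
    """
    genes: list[SpidroinGene] = []
    unpaired_ntds: list[TerminalDomainCall] = []
    used: set[int] = set()

    groups: dict[tuple[str, str], list[TerminalDomainCall]] = {}
    for n in ntds:
        groups.setdefault((n.interval.scaffold, n.interval.strand), []).append(n)
    ctd_by_group: dict[tuple[str, str], list[tuple[int, TerminalDomainCall]]] = {}
    for j, c in enumerate(ctds):
        ctd_by_group.setdefault((c.interval.scaffold, c.interval.strand), []).append((j, c))

    for key, group_ntds in groups.items():
        _, strand = key
        cands = ctd_by_group.get(key, [])
        if strand == "+":
            group_ntds.sort(key=lambda n: n.interval.start)
        else:
            group_ntds.sort(key=lambda n: -n.interval.end)
        for ntd in group_ntds:
            best = None
            for j, ctd in cands:
                if j in used:
                    continue
                if strand == "+":
                    if ctd.interval.start < ntd.interval.end:
                        continue
                    dist = ctd.interval.start - ntd.interval.end
                else:
                    if ctd.interval.end > ntd.interval.start:
                        continue
                    dist = ntd.interval.start - ctd.interval.end
                if best is None or dist < best[0]:
                    best = (dist, j, ctd)
            if best is None:
                unpaired_ntds.append(ntd)
                continue
            _, j, ctd = best
            lo = min(ntd.interval.start, ctd.interval.start)
            hi = max(ntd.interval.end, ctd.interval.end)
            if hi - lo > max_gene_span:
                unpaired_ntds.append(ntd)
                continue
            used.add(j)
            genes.append(
                SpidroinGene(
                    interval=GenomicInterval(ntd.interval.scaffold, lo, hi, strand),
                    ntd=ntd,
                    ctd=ctd,
                    final_class=classify_gene(ntd.class_label, ctd.class_label),
                )
            )
    unpaired_ctds = [c for j, c in enumerate(ctds) if j not in used]
    genes.sort(key=lambda g: (g.interval.scaffold, g.interval.start))
    return genes, unpaired_ntds, unpaired_ctds


def extract_candidate_ctd(
    seq: str, region_start: int, frame: int, strand: str = "+"
) -> str:
    """Extract the <= 500 bp immediately upstream of the first in-frame stop.

    Walks codons on the given strand starting at or after ``region_start``
    (forward-strand coordinate) in reading frame ``frame`` (offset of codon
    starts from the oriented sequence start, modulo 3); at the first stop
    codon (TAA/TAG/TGA) returns the 500 bases before its first base, fewer
    if the sequence begins closer than 500 bp.
    """
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    if not (0 <= region_start < len(seq)):
        raise ValueError("region_start outside sequence")
    oriented = seq if strand == "+" else revcomp(seq)
    start = region_start if strand == "+" else len(seq) - region_start
    p = start + (frame - start) % 3
    while p + 3 <= len(oriented):
        if oriented[p : p + 3] in STOP_CODONS:
            return oriented[max(0, p - 500) : p]
        p += 3
    raise ValueError("no stop in frame")


def summarize_repertoire(
    species: str,
    genes: list[SpidroinGene],
    unpaired_ntds: list[TerminalDomainCall],
    unpaired_ctds: list[TerminalDomainCall],
) -> RepertoireSummary:
    """Per-class gene counts and length statistics for one species."""
    counts: dict[str, int] = {}
    by_class: dict[str, list[int]] = {}
    for g in genes:
        counts[g.final_class] = counts.get(g.final_class, 0) + 1
        by_class.setdefault(g.final_class, []).append(g.span_bp)
    return RepertoireSummary(
        species=species,
        counts=counts,
        gene_lengths=[g.span_bp for g in genes],
        median_length_by_class={k: float(median(v)) for k, v in by_class.items()},
        n_unpaired_ntds=len(unpaired_ntds),
        n_unpaired_ctds=len(unpaired_ctds),
    )


def genes_to_gff3(genes: list[SpidroinGene]) -> list[Gff3Feature]:
    """Gene + child terminal-domain features with Parent linkage."""
    feats: list[Gff3Feature] = []
    for i, g in enumerate(genes):
        gid = f"spidroin{i + 1:04d}"
        feats.append(
            Gff3Feature(
                g.interval,
                "spidroin_gene",
                attributes={"ID": gid, "spidroin_class": g.final_class},
            )
        )
        for call in (g.ntd, g.ctd):
            feats.append(
                Gff3Feature(
                    call.interval,
                    "terminal_domain",
                    score=call.bit_score,
                    attributes={
                        "Parent": gid,
                        "terminus": call.terminus,
                        "domain_class": call.class_label,
                        "evalue": f"{call.evalue:.3g}",
                    },
                )
            )
    return feats
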