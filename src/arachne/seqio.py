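"""Sequence, alignment, tree and annotation file I/O.

Coordinate conventions
----------------------
All in-memory intervals are 0-based half-open (``start`` inclusive,
``end`` exclusive).  GFF3 files are written 1-based inclusive, the single
place where the conversion (``start + 1``) happens; reading converts back.
"""

from __future__ import annotations

import urllib.parse
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import AlignIO, SeqIO

__all__ = [
    "SequenceRecord",
    "MultipleAlignment",
    "GenomicInterval",
    "Gff3Feature",
    "read_fasta",
    "write_fasta",
    "read_alignment",
    "write_alignment",
    "write_gff3",
    "read_gff3",
    "read_newick",
    "revcomp",
]

_VALID = set("ACGTN")
_RC = str.maketrans("ACGTN", "TGCAN")


def _normalise(seq: str) -> str:
    """Uppercase and collapse IUPAC ambiguity codes outside {A,C,G,T,N} to N."""
    s = seq.upper()
    if set(s) <= _VALID:
        return s
    return "".join(c if c in _VALID else "N" for c in s)


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass
class SequenceRecord:
    """A single DNA sequence (genome scaffold, domain, ...)."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if len(self.residues) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class MultipleAlignment:
    """Equal-length gapped rows over {A,C,G,T,N,-}."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("alignment needs at least 2 rows")
        n = len(self.rows[0])
        if any(len(r) != n for r in self.rows):
            raise ValueError("alignment rows have unequal lengths")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def column(self, j: int) -> str:
        return "".join(r[j] for r in self.rows)

    def slice_columns(self, start: int, end: int) -> "MultipleAlignment":
        return MultipleAlignment(list(self.ids), [r[start:end] for r in self.rows])


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a named scaffold."""

    scaffold: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.scaffold}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.scaffold == other.scaffold
            and self.start < other.end
            and other.start < self.end
        )


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a DNA FASTA file.

    Lowercase bases are uppercased; IUPAC codes outside {A,C,G,T,N} map to N.
    Duplicate ids and empty files are errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, _normalise(str(rec.seq)), rec.description))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description or rec.description == rec.id else (
                f"{rec.id} {rec.description}" if not rec.description.startswith(rec.id) else rec.description
            )
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def read_alignment(path: str | Path) -> MultipleAlignment:
    aln = AlignIO.read(str(path), "fasta")
    ids = [r.id for r in aln]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate row id in alignment {path}")
    rows = []
    for r in aln:
        s = str(r.seq).upper()
        rows.append("".join(c if c in _VALID or c == "-" else "N" for c in s))
    return MultipleAlignment(ids, rows)


def write_alignment(aln: MultipleAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, row in zip(aln.ids, aln.rows):
            fh.write(f">{rid}\n{row}\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_GFF_ESCAPE_SAFE = "".join(
    c for c in map(chr, range(33, 127)) if c not in "=;,&\t%"
)


@dataclass
class Gff3Feature:
    interval: GenomicInterval
    type: str
    source: str = "arachne"
    score: float | None = None
    attributes: dict[str, str] = field(default_factory=dict)


def _esc(value: str) -> str:
    return urllib.parse.quote(value, safe=_GFF_ESCAPE_SAFE + " ")


def write_gff3(
    features: Sequence[Gff3Feature],
    path: str | Path,
    scaffold_lengths: dict[str, int] | None = None,
) -> None:
    """Write features as GFF3 (1-based inclusive coordinates).

    If ``scaffold_lengths`` is given, intervals beyond a scaffold end are an
    error and ``##sequence-region`` pragmas are emitted.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if scaffold_lengths:
            for name, length in scaffold_lengths.items():
                fh.write(f"##sequence-region {name} 1 {length}\n")
        for f in features:
            iv = f.interval
            if scaffold_lengths is not None and iv.scaffold in scaffold_lengths:
                if iv.end > scaffold_lengths[iv.scaffold]:
                    raise ValueError(
                        f"feature end {iv.end} beyond scaffold "
                        f"{iv.scaffold} length {scaffold_lengths[iv.scaffold]}"
                    )
            score = "." if f.score is None else f"{f.score:g}"
            attrs = ";".join(f"{_esc(k)}={_esc(v)}" for k, v in f.attributes.items()) or "."
            fh.write(
                f"{iv.scaffold}\t{f.source}\t{f.type}\t{iv.start + 1}\t{iv.end}\t"
                f"{score}\t{iv.strand}\t.\t{attrs}\n"
            )


def read_gff3(path: str | Path) -> list[Gff3Feature]:
    feats: list[Gff3Feature] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line in {path}: {line!r}")
            scaffold, source, ftype, start, end, score, strand, _phase, attrs = cols
            attributes = {}
            if attrs != ".":
                for pair in attrs.split(";"):
                    if not pair:
                        continue
                    k, _, v = pair.partition("=")
                    attributes[urllib.parse.unquote(k)] = urllib.parse.unquote(v)
            feats.append(
                Gff3Feature(
                    GenomicInterval(scaffold, int(start) - 1, int(end), strand),
                    ftype,
                    source,
                    None if score == "." else float(score),
                    attributes,
                )
            )
    return feats


def read_newick(path: str | Path):
    """Read a rooted, branch-length-bearing newick tree.

    Returns an :class:`arachne.ancestral.Phylogeny`.  The tree must be rooted
    (bifurcating root) and every non-root edge must carry a branch length.
    """
    from arachne.ancestral import Phylogeny  # local import avoids a cycle

    return Phylogeny.from_newick_file(path)
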