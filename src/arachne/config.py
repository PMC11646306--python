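"""Run configuration: thresholds, calibration settings, paths.

Defaults are the published operating point of the annotation procedure:
spidroin hits at E < 1e-10 with >= 90% model coverage, a 100 kbp gene span
cap, hox hits at E < 1e-20, a 5 Mbp separated-copy gap threshold, 1 kbp hox
hit merging and a 10 kbp scaffold-edge window for fragmented clusters.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from arachne.hox import ANCESTRAL_ORDER

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    seed: int = 42
    # thresholds
    spidroin_evalue: float = 1e-10
    min_model_cov: float = 0.90
    max_gene_span: int = 100_000
    hox_evalue: float = 1e-20
    gap_threshold_bp: int = 5_000_000
    merge_bp: int = 1_000
    edge_bp: int = 10_000
    evalue_report: float = 10.0
    # calibration
    calib_n_seqs: int = 200
    calib_seq_len: int = 1_000
    # ancestral gene order
    ancestral_order: tuple[str, ...] = ANCESTRAL_ORDER
    # paths (optional; synthetic runs generate their own inputs)
    genome: str | None = None
    references: str | None = None
    tree: str | None = None
    outdir: str = "results/run"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = {
            "spidroin_evalue": self.spidroin_evalue,
            "min_model_cov": self.min_model_cov,
            "max_gene_span": self.max_gene_span,
            "hox_evalue": self.hox_evalue,
            "gap_threshold_bp": self.gap_threshold_bp,
            "merge_bp": self.merge_bp,
            "edge_bp": self.edge_bp,
            "evalue_report": self.evalue_report,
            "calib_n_seqs": self.calib_n_seqs,
            "calib_seq_len": self.calib_seq_len,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ValueError(f"config threshold {name} must be positive, got {value}")
        if not 0 < self.min_model_cov <= 1:
            raise ValueError("min_model_cov must be in (0, 1]")
        if len(self.ancestral_order) != len(set(self.ancestral_order)):
            raise ValueError("ancestral_order contains duplicates")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ancestral_order"] = list(self.ancestral_order)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "ancestral_order" in data:
            data["ancestral_order"] = tuple(data["ancestral_order"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
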