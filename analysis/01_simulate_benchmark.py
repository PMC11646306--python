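#!/usr/bin/env python
"""Generate the synthetic benchmark: reference sets, genome, planted truth.

Conditions: ~2 Mbp of i.i.d. background DNA (GC 0.35) carrying 24 spidroin
genes across 6 classes at 10% divergence from their class consensi, plus
two hox clusters — an intact A copy and a B copy with ftz absent, one Hox3
loss, one Dfd tandem duplication and one inversion.  Everything lands in
results/analysis/data/ for the downstream steps.
"""

from pathlib import Path

from arachne import hmm, simulate
from arachne.config import RunConfig
from arachne.seqio import write_alignment, write_fasta

OUT = Path("results/analysis/data")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = RunConfig(seed=42)
    spec = simulate.default_benchmark_spec(seed=cfg.seed)

    classes = sorted({p.spidroin_class for p in spec.spidroins})
    alns, consensus = simulate.make_reference_set(
        classes, seed=(cfg.seed * 7 + 1) % (2**31)
    )
    hox_alns, hox_consensus = simulate.make_reference_set(
        hmm.HOX_GENES, domain_len=simulate.HOX_DOMAIN_LEN,
        seed=(cfg.seed * 7 + 2) % (2**31), termini=("none",),
    )

    genome, truth = simulate.simulate_genome(spec, consensus, hox_consensus)
    write_fasta(genome, OUT / "genome.fa")
    refdir = OUT / "references"
    refdir.mkdir(exist_ok=True)
    for (cls, term), aln in {**alns, **hox_alns}.items():
        write_alignment(aln, refdir / f"{cls}_{term}.afa")
    truth.write(OUT)
    cfg.to_yaml(OUT / "config.yaml")

    n_bp = sum(len(r) for r in genome)
    print(f"wrote {len(genome)} scaffolds, {n_bp/1e6:.2f} Mbp -> {OUT}/genome.fa")
    print(f"planted {len(truth.genes)} spidroin genes "
          f"({len(truth.domains)} terminal domains), "
          f"{len(truth.hox_genes)} hox genes in {len(truth.clusters)} clusters")


if __name__ == "__main__":
    main()
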