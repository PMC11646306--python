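"""Stage orchestration: simulate -> build -> calibrate -> scan -> annotate -> evaluate.

Each stage writes its documented artifacts plus a ``manifest.json`` (config
hash, seed, input/output file hashes, package version) sufficient to verify
a bit-identical re-run.  All randomness is seeded from the run config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

import arachne
from arachne import hmm, hox, simulate, spidroin
from arachne.config import RunConfig
from arachne.seqio import Gff3Feature, write_alignment, write_fasta, write_gff3

logger = logging.getLogger(__name__)

__all__ = [
    "build_profiles",
    "scan_genome",
    "annotate_spidroins",
    "annotate_hox",
    "run_all",
    "write_manifest",
]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir: Path, config: RunConfig, inputs: list[Path],
                   outputs: list[Path]) -> Path:
    cfg_json = json.dumps(config.to_dict(), sort_keys=True)
    manifest = {
        "arachne_version": arachne.__version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "config": config.to_dict(),
        "inputs": {str(p): _sha256(Path(p)) for p in inputs},
        "outputs": {Path(p).name: _sha256(Path(p)) for p in outputs},
    }
    path = Path(outdir) / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return path


def build_profiles(
    alignments: dict, config: RunConfig, calibrate: bool = True
) -> dict:
    """Trim, build and (optionally) calibrate one profile per alignment.

    ``alignments`` maps (class_label, terminus) to a MultipleAlignment.
    Calibration seeds derive deterministically from the run seed and the
    sorted key order.
    """
    profiles = {}
    for i, key in enumerate(sorted(alignments)):
        cls, term = key
        aln = hmm.trim_conserved(alignments[key])
        prof = hmm.build_profile(aln, model_id=f"{cls}_{term}", class_label=cls,
                                 terminus=term)
        if calibrate:
            hmm.calibrate(
                prof,
                n_seqs=config.calib_n_seqs,
                seq_len=config.calib_seq_len,
                seed=(config.seed * 1_000 + i) % (2**31),
            )
        profiles[key] = prof
    return profiles


def scan_genome(profiles: dict, genome, config: RunConfig) -> list[hmm.HmmHit]:
    hits: list[hmm.HmmHit] = []
    for key in sorted(profiles):
        hits.extend(hmm.scan(profiles[key], genome, config.evalue_report))
    return hits


def annotate_spidroins(hits: list[hmm.HmmHit], config: RunConfig):
    """Filter, resolve, pair and classify spidroin terminal-domain hits."""
    kept = spidroin.filter_hits(hits, config.spidroin_evalue, config.min_model_cov)
    ntds = spidroin.resolve_overlaps(kept, "NTD")
    ctds = spidroin.resolve_overlaps(kept, "CTD")
    return spidroin.pair_terminals(ntds, ctds, config.max_gene_span)


def annotate_hox(
    hits: list[hmm.HmmHit],
    scaffold_lengths: dict[str, int],
    config: RunConfig,
):
    """Call hox loci, partition and label clusters, count rearrangements."""
    calls = hox.call_hox_genes(hits, config.hox_evalue, config.merge_bp)
    clusters = hox.partition_clusters(calls, config.gap_threshold_bp)
    hox.label_clusters(clusters)
    reports = {}
    for cl in clusters:
        hox.flag_fragmented(
            cl, scaffold_lengths[cl.scaffold], config.ancestral_order, config.edge_bp
        )
        if cl.label in ("A", "B") and not cl.fragmented and len(cl.calls) >= 2:
            reports[cl.cluster_id] = hox.count_rearrangements(
                cl, config.ancestral_order
            )
    return calls, clusters, reports


def _cluster_frame(clusters) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cluster_id": cl.cluster_id,
                "scaffold": cl.scaffold,
                "label": cl.label,
                "members": ",".join(cl.members),
                "fragmented": cl.fragmented,
                "separated_copies": ",".join(c.gene for c in cl.separated_copies),
            }
            for cl in clusters
        ],
        columns=["cluster_id", "scaffold", "label", "members", "fragmented",
                 "separated_copies"],
    )


def run_all(
    config: RunConfig,
    spec: simulate.SimulationSpec | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Full synthetic pipeline; returns the evaluation metrics.

    Simulates a genome from ``spec`` (default benchmark conditions when
    omitted, reseeded from the config), trains and calibrates profiles from
    the simulated reference sets, scans, annotates spidroins and hox
    clusters, and scores everything against the planted truth.  Artifacts
    and a manifest land in ``outdir`` when given.
    """
    if spec is None:
        spec = simulate.default_benchmark_spec(seed=config.seed)
    out = Path(outdir or config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    classes = sorted({p.spidroin_class for p in spec.spidroins})
    ref_alignments, consensus = simulate.make_reference_set(
        classes, seed=(config.seed * 7 + 1) % (2**31)
    )
    hox_alignments, hox_consensus = ({}, {})
    if spec.hox_clusters:
        hox_alignments, hox_consensus = simulate.make_reference_set(
            hmm.HOX_GENES,
            domain_len=simulate.HOX_DOMAIN_LEN,
            seed=(config.seed * 7 + 2) % (2**31),
            termini=("none",),
        )
    genome, truth = simulate.simulate_genome(spec, consensus, hox_consensus)
    scaffold_lengths = {r.id: len(r) for r in genome}

    logger.info("building %d profiles", len(ref_alignments) + len(hox_alignments))
    profiles = build_profiles({**ref_alignments, **hox_alignments}, config)

    logger.info("scanning %d scaffolds (%.2f Mbp)", len(genome),
                sum(scaffold_lengths.values()) / 1e6)
    hits = scan_genome(profiles, genome, config)
    spid_hits = [h for h in hits if h.terminus in ("NTD", "CTD")]
    hox_hits = [h for h in hits if h.terminus == "none"]

    genes, unpaired_ntds, unpaired_ctds = annotate_spidroins(spid_hits, config)
    hox_calls, clusters, reports = annotate_hox(hox_hits, scaffold_lengths, config)
    reports_by_name = _reports_by_planted_name(clusters, reports, truth)

    metrics = simulate.evaluate_recovery(
        truth,
        genes=genes,
        hox_calls=hox_calls,
        cluster_reports=reports_by_name,
    )
    summary = spidroin.summarize_repertoire(
        "synthetic", genes, unpaired_ntds, unpaired_ctds
    )
    metrics["repertoire"] = {
        "counts": summary.counts,
        "n_unpaired_ntds": summary.n_unpaired_ntds,
        "n_unpaired_ctds": summary.n_unpaired_ctds,
    }

    # ----- artifacts -----
    outputs = []

    def _save(name: str, writer) -> None:
        p = out / name
        writer(p)
        outputs.append(p)

    _save("genome.fa", lambda p: write_fasta(genome, p))
    refdir = out / "references"
    refdir.mkdir(exist_ok=True)
    for (cls, term), aln in {**ref_alignments, **hox_alignments}.items():
        fp = refdir / f"{cls}_{term}.afa"
        write_alignment(aln, fp)
        outputs.append(fp)
    profdir = out / "profiles"
    profdir.mkdir(exist_ok=True)
    for key, prof in profiles.items():
        fp = profdir / f"{prof.model_id}.json"
        hmm.profile_to_json(prof, fp)
        outputs.append(fp)
    truth.write(out)
    outputs += sorted(out.glob("truth_*.tsv"))
    _save("hits.tsv", lambda p: hmm.hits_to_frame(hits).to_csv(p, sep="\t", index=False))
    _save(
        "spidroins.gff3",
        lambda p: write_gff3(spidroin.genes_to_gff3(genes), p, scaffold_lengths),
    )
    _save(
        "hox_calls.gff3",
        lambda p: write_gff3(
            [
                Gff3Feature(c.interval, "homeobox", score=c.bit_score,
                            attributes={"gene": c.gene, "evalue": f"{c.evalue:.3g}"})
                for c in hox_calls
            ],
            p,
            scaffold_lengths,
        ),
    )
    _save(
        "hox_clusters.tsv",
        lambda p: _cluster_frame(clusters).to_csv(p, sep="\t", index=False),
    )
    _save(
        "rearrangements.tsv",
        lambda p: pd.DataFrame(
            [
                {"cluster_id": cid, "losses": r.losses,
                 "tandem_duplications": r.tandem_duplications,
                 "inversions": r.inversions, "unexplained": r.unexplained,
                 "total": r.total}
                for cid, r in sorted(reports.items())
            ],
            columns=["cluster_id", "losses", "tandem_duplications", "inversions",
                     "unexplained", "total"],
        ).to_csv(p, sep="\t", index=False),
    )
    _save(
        "evaluation.json",
        lambda p: p.write_text(json.dumps(metrics, indent=1, sort_keys=True)),
    )
    write_manifest(out, config, inputs=[], outputs=outputs)
    return metrics


def _reports_by_planted_name(clusters, reports, truth) -> dict:
    """Map planted cluster names to reports via scaffold identity."""
    by_scaffold = {}
    for cl in clusters:
        if cl.cluster_id in reports:
            by_scaffold[cl.scaffold] = reports[cl.cluster_id]
    return {
        row["cluster"]: by_scaffold[row["scaffold"]]
        for row in truth.clusters
        if row["scaffold"] in by_scaffold
    }
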