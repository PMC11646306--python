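import numpy as np
import pytest

from arachne import hmm, simulate
from arachne.seqio import GenomicInterval


@pytest.fixture(scope="session")
def small_refs():
    """Two spidroin classes, short domains — cheap profile training data."""
    return simulate.make_reference_set(
        ["MaSp", "MiSp"], n_seqs_per_class=12, domain_len=60, seed=11
    )


@pytest.fixture(scope="session")
def small_profile(small_refs):
    """A calibrated MaSp NTD profile over a 60 bp domain."""
    alns, _ = small_refs
    prof = hmm.build_profile(
        hmm.trim_conserved(alns[("MaSp", "NTD")]), "MaSp_NTD", "MaSp", "NTD"
    )
    return hmm.calibrate(prof, n_seqs=150, seq_len=800, seed=3)


def make_hit(
    scaffold="s1",
    start=100,
    end=250,
    strand="+",
    class_label="MaSp",
    terminus="NTD",
    evalue=1e-15,
    bit_score=80.0,
    bias_score=2.0,
    model_cov=0.97,
):
    return hmm.HmmHit(
        model_id=f"{class_label}_{terminus}",
        class_label=class_label,
        terminus=terminus,
        interval=GenomicInterval(scaffold, start, end, strand),
        bit_score=bit_score,
        bias_score=bias_score,
        evalue=evalue,
        model_cov=model_cov,
        ali_from=1,
        ali_to=int(model_cov * 100),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
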