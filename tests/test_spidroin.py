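"""Spidroin annotation: filtering, overlap resolution, pairing, classification."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import component_best_calls, first_stop_upstream
from arachne import spidroin
from arachne.seqio import GenomicInterval
from conftest import make_hit


class TestFilterHits:
    def test_all_criteria_pass(self):
        h = make_hit(evalue=1e-12, bit_score=50, bias_score=3, model_cov=0.95)
        assert spidroin.filter_hits([h]) == [h]

    def test_evalue_threshold_is_strict(self):
        h = make_hit(evalue=1e-9, bit_score=50, bias_score=3, model_cov=0.95)
        assert spidroin.filter_hits([h]) == []

    def test_bit_equal_bias_removed(self):
        h = make_hit(evalue=1e-12, bit_score=3, bias_score=3, model_cov=0.95)
        assert spidroin.filter_hits([h]) == []

    def test_coverage_below_90_removed(self):
        h = make_hit(evalue=1e-12, bit_score=50, bias_score=3, model_cov=0.89)
        assert spidroin.filter_hits([h]) == []

    def test_coverage_exactly_90_kept(self):
        h = make_hit(model_cov=0.90)
        assert spidroin.filter_hits([h]) == [h]

    def test_order_preserved(self):
        hits = [make_hit(start=s, end=s + 100) for s in (500, 100, 300)]
        assert spidroin.filter_hits(hits) == hits


class TestResolveOverlaps:
    def test_lowest_evalue_wins(self):
        a = make_hit(class_label="MaSp", evalue=1e-15, start=100, end=250)
        b = make_hit(class_label="MiSp", evalue=1e-12, start=200, end=350)
        calls = spidroin.resolve_overlaps([a, b], "NTD")
        assert len(calls) == 1
        assert calls[0].class_label == "MaSp"

    def test_single_hit_identity(self):
        a = make_hit()
        calls = spidroin.resolve_overlaps([a], "NTD")
        assert len(calls) == 1
        assert calls[0].interval == a.interval

    def test_transitive_chain(self):
        a = make_hit(class_label="AcSp", evalue=1e-11, start=100, end=200)
        b = make_hit(class_label="MaSp", evalue=1e-20, start=180, end=300)
        c = make_hit(class_label="MiSp", evalue=1e-13, start=280, end=400)
        calls = spidroin.resolve_overlaps([a, b, c], "NTD")
        assert len(calls) == 1
        assert calls[0].class_label == "MaSp"

    def test_opposite_strands_stay_separate(self):
        a = make_hit(strand="+", start=100, end=250)
        b = make_hit(strand="-", start=120, end=270, class_label="MiSp")
        assert len(spidroin.resolve_overlaps([a, b], "NTD")) == 2

    @pytest.mark.parametrize("n_hits", [2, 3, 4])
    def test_matches_component_oracle_exhaustively(self, n_hits):
        """Agreement with a transitive-closure/argmin oracle over all
        start-position configurations of up to 4 hits."""
        classes = ["MaSp", "MiSp", "AcSp", "Flag"]
        starts_options = [0, 80, 160, 400]
        for combo in itertools.product(starts_options, repeat=n_hits):
            hits = [
                make_hit(
                    class_label=classes[i],
                    start=s + i,  # avoid exact ties in coordinates
                    end=s + i + 100,
                    evalue=10.0 ** -(11 + 3 * i),
                )
                for i, s in enumerate(combo)
            ]
            calls = spidroin.resolve_overlaps(hits, "NTD")
            expected = component_best_calls(hits)
            got = sorted((c.interval.start, c.class_label) for c in calls)
            want = sorted((h.interval.start, h.class_label) for h in expected)
            assert got == want

    def test_no_retained_overlap_invariant(self, rng):
        hits = [
            make_hit(
                start=int(s),
                end=int(s) + int(rng.integers(50, 200)),
                class_label=["MaSp", "MiSp", "AcSp"][int(rng.integers(3))],
                evalue=float(10.0 ** -rng.uniform(11, 30)),
            )
            for s in rng.integers(0, 2000, size=30)
        ]
        calls = spidroin.resolve_overlaps(hits, "NTD")
        for a, b in itertools.combinations(calls, 2):
            assert not (
                a.interval.strand == b.interval.strand
                and a.interval.overlaps(b.interval)
            )


def _call(start, end, terminus, cls="MaSp", scaffold="s1", strand="+"):
    return spidroin.TerminalDomainCall(
        interval=GenomicInterval(scaffold, start, end, strand),
        terminus=terminus,
        class_label=cls,
        evalue=1e-15,
        bit_score=80.0,
        bias_score=2.0,
        model_cov=0.97,
    )


class TestPairTerminals:
    def test_basic_pair(self):
        genes, un_n, un_c = spidroin.pair_terminals(
            [_call(1000, 1150, "NTD")], [_call(9000, 9150, "CTD")]
        )
        assert len(genes) == 1
        g = genes[0]
        assert (g.interval.start, g.interval.end) == (1000, 9150)
        assert g.span_bp == 8150
        assert not un_n and not un_c

    def test_over_span_pair_discarded(self):
        genes, un_n, un_c = spidroin.pair_terminals(
            [_call(1000, 1150, "NTD")], [_call(150_000, 150_150, "CTD")]
        )
        assert genes == []
        assert len(un_n) == 1 and len(un_c) == 1

    def test_lone_ntd_unpaired(self):
        genes, un_n, un_c = spidroin.pair_terminals([_call(1000, 1150, "NTD")], [])
        assert genes == []
        assert len(un_n) == 1 and un_c == []

    def test_minus_strand_downstream_is_leftward(self):
        ntd = _call(50_000, 50_150, "NTD", strand="-")
        ctd = _call(42_000, 42_150, "CTD", strand="-")
        genes, _, _ = spidroin.pair_terminals([ntd], [ctd])
        assert len(genes) == 1
        assert genes[0].interval.strand == "-"
        assert (genes[0].interval.start, genes[0].interval.end) == (42_000, 50_150)

    def test_opposite_strand_never_pairs(self):
        genes, un_n, un_c = spidroin.pair_terminals(
            [_call(1000, 1150, "NTD", strand="+")],
            [_call(9000, 9150, "CTD", strand="-")],
        )
        assert genes == []

    def test_ctd_used_at_most_once(self):
        ntds = [_call(1000, 1150, "NTD"), _call(5000, 5150, "NTD")]
        ctds = [_call(9000, 9150, "CTD")]
        genes, un_n, _ = spidroin.pair_terminals(ntds, ctds)
        assert len(genes) == 1
        assert genes[0].ntd.interval.start == 1000  # 5' NTD claims it first
        assert len(un_n) == 1

    def test_gene_invariants(self, rng):
        ntds = [
            _call(int(s), int(s) + 150, "NTD")
            for s in sorted(rng.integers(0, 500_000, size=10))
        ]
        ctds = [
            _call(int(s), int(s) + 150, "CTD")
            for s in sorted(rng.integers(0, 500_000, size=10))
        ]
        genes, _, _ = spidroin.pair_terminals(ntds, ctds)
        for g in genes:
            assert g.span_bp <= 100_000
            assert g.ntd.interval.start <= g.ctd.interval.start  # plus strand


class TestClassifyGene:
    @pytest.mark.parametrize(
        "ntd,ctd,expected",
        [
            ("MaSp", "MaSp", "MaSp"),
            ("MaSp", "unclassified", "MaSp"),
            ("unclassified", "MiSp", "MiSp"),
            ("MaSp", "MiSp", "discordant"),
            ("unclassified", "unclassified", "unclassified"),
            ("MaSp", "MesCTD", "MaSp"),
            ("unclassified", "MesCTD", "unclassified"),
        ],
    )
    def test_rules(self, ntd, ctd, expected):
        assert spidroin.classify_gene(ntd, ctd) == expected

    def test_unknown_label_errors(self):
        with pytest.raises(ValueError, match="unknown"):
            spidroin.classify_gene("MaSp", "NotAClass")

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        a=st.sampled_from(sorted(spidroin.CLASS_VOCAB)),
        b=st.sampled_from(sorted(spidroin.CLASS_VOCAB)),
    )
    def test_wildcard_symmetry(self, a, b):
        """classify(x, wildcard) behaves like classify(wildcard, x)."""
        assert spidroin.classify_gene(a, b) == spidroin.classify_gene(b, a)


class TestExtractCandidateCtd:
    def test_500bp_upstream_of_stop(self, rng):
        body = "".join("ACG"[c] for c in rng.integers(0, 3, 600))  # stop-free
        seq = body + "TAA" + "CCCCCC"
        out = spidroin.extract_candidate_ctd(seq, 0, frame=0)
        assert out == seq[100:600]
        assert len(out) == 500

    def test_truncated_when_near_start(self, rng):
        body = "".join("ACG"[c] for c in rng.integers(0, 3, 300))
        seq = body + "TGA"
        out = spidroin.extract_candidate_ctd(seq, 0, frame=0)
        assert out == seq[:300]

    def test_no_stop_errors(self):
        with pytest.raises(ValueError, match="no stop"):
            spidroin.extract_candidate_ctd("ACA" * 100, 0, frame=0)

    @pytest.mark.parametrize("frame", [0, 1, 2])
    def test_matches_codon_walk_oracle(self, frame, rng):
        for trial in range(20):
            r = np.random.default_rng(trial)
            seq = "".join("ACGT"[c] for c in r.integers(0, 4, 900))
            start = int(r.integers(0, 300))
            try:
                expected = first_stop_upstream(seq, start, frame)
            except ValueError:
                with pytest.raises(ValueError):
                    spidroin.extract_candidate_ctd(seq, start, frame)
                continue
            assert spidroin.extract_candidate_ctd(seq, start, frame) == expected


class TestSummarize:
    def test_empty(self):
        s = spidroin.summarize_repertoire("sp", [], [], [])
        assert s.counts == {} and s.n_genes == 0

    def test_counts(self):
        genes, _, _ = spidroin.pair_terminals(
            [_call(s, s + 150, "NTD", cls=c) for s, c in
             [(1000, "MaSp"), (20_000, "MaSp"), (40_000, "MaSp"), (60_000, "MaSp")]],
            [_call(s, s + 150, "CTD", cls=c) for s, c in
             [(9000, "MaSp"), (28_000, "MaSp"), (48_000, "MaSp"), (68_000, "MiSp")]],
        )
        s = spidroin.summarize_repertoire("sp", genes, [], [])
        assert s.counts == {"MaSp": 3, "discordant": 1}
        assert s.n_genes == 4
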