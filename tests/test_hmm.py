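"""Profile engine: trimming, training, Viterbi, calibration, scanning."""

import numpy as np
import pytest

from _oracles import brute_force_viterbi
from arachne import hmm
from arachne.seqio import MultipleAlignment, SequenceRecord, revcomp
from arachne.simulate import make_reference_set, mutate


def _aln(rows):
    return MultipleAlignment([f"r{i}" for i in range(len(rows))], rows)


def _random_profile(rng, M, alphabet_skew=3.0):
    """Small random profile built from a sampled alignment."""
    cons = "".join("ACGT"[c] for c in rng.integers(0, 4, M))
    rows = [mutate(cons, 0.1, rng) for _ in range(8)]
    return hmm.build_profile(_aln(rows), "rand", "X", "NTD")


class TestTrimConserved:
    def test_identical_alignment_unchanged(self):
        aln = _aln(["ACGTACGTACGT"] * 4)
        out = hmm.trim_conserved(aln, window=10)
        assert out.rows == aln.rows

    def test_random_flanks_cropped(self, rng):
        core = "".join("ACGT"[c] for c in rng.integers(0, 4, 50))
        rows = []
        for _ in range(8):
            left = "".join("ACGT"[c] for c in rng.integers(0, 4, 20))
            right = "".join("ACGT"[c] for c in rng.integers(0, 4, 20))
            rows.append(left + core + right)
        out = hmm.trim_conserved(_aln(rows))
        assert 50 <= out.n_columns <= 70

    def test_unrelated_rows_error(self):
        r = np.random.default_rng(2)
        rows = ["".join("ACGT"[c] for c in r.integers(0, 4, 80)) for _ in range(2)]
        with pytest.raises(ValueError, match="no conserved core"):
            hmm.trim_conserved(_aln(rows))


class TestBuildProfile:
    def test_pseudocount_emissions(self):
        aln = _aln(["ACGTACGT"] * 4)
        prof = hmm.build_profile(aln, "m")
        assert prof.M == 8
        # 4 observed + 1 pseudocount over 4 + 4
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        for k, base in enumerate("ACGTACGT"):
            assert prof.match_emissions[k, idx[base]] == pytest.approx(5 / 8)

    def test_majority_gapped_column_not_match(self):
        rows = ["AAAAA-AAAA", "AAAAA-AAAA", "AAAAA-AAAA", "AAAAACAAAA"]
        prof = hmm.build_profile(_aln(rows), "m")
        assert prof.M == 9  # the 3/4-gapped column is an insert column

    def test_rows_normalised(self, rng):
        prof = _random_profile(rng, 30)
        assert np.allclose(prof.match_emissions.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(prof.tMM + prof.tMI + prof.tMD, 1.0, atol=1e-9)
        assert np.allclose(prof.tIM + prof.tII, 1.0, atol=1e-9)
        assert np.allclose(prof.tDM + prof.tDD, 1.0, atol=1e-9)

    def test_too_few_match_columns_errors(self):
        with pytest.raises(ValueError, match="match columns"):
            hmm.build_profile(_aln(["ACGT"] * 3), "m")


class TestViterbi:
    @pytest.mark.parametrize("trial", range(12))
    def test_matches_brute_force_enumeration(self, trial):
        """Exact agreement with exhaustive path enumeration (M<=6, L<=12)."""
        rng = np.random.default_rng(100 + trial)
        cons = "".join("ACGT"[c] for c in rng.integers(0, 4, 6))
        rows = [mutate(cons, 0.2, rng) for _ in range(5)]
        prof = hmm.build_profile(_aln(rows), "m")
        L = int(rng.integers(5, 13))
        seq = "".join("ACGT"[c] for c in rng.integers(0, 4, L))
        score, _, _ = hmm.viterbi_score(prof, seq)
        assert score == pytest.approx(brute_force_viterbi(prof, seq), abs=1e-9)

    def test_consensus_beats_training_rows(self, rng):
        """Profile consensus scores at least as high as any training row."""
        for trial in range(20):
            r = np.random.default_rng(trial)
            cons = "".join("ACGT"[c] for c in r.integers(0, 4, 40))
            rows = [mutate(cons, 0.15, r) for _ in range(6)]
            prof = hmm.build_profile(_aln(rows), "m")
            c_score, _, _ = hmm.viterbi_score(prof, prof.consensus())
            for row in rows:
                s, _, _ = hmm.viterbi_score(prof, row)
                assert c_score >= s - 1e-9

    def test_all_n_sequence_scores_zero(self, small_profile):
        score, seq_span, _ = hmm.viterbi_score(small_profile, "N" * 200)
        assert score <= 0
        assert seq_span == (0, 0)

    def test_exact_consensus_covers_full_model(self, rng):
        for trial in range(5):
            r = np.random.default_rng(200 + trial)
            cons = "".join("ACGT"[c] for c in r.integers(0, 4, 10))
            rows = [cons] * 5
            prof = hmm.build_profile(_aln(rows), "m")
            _, _, (k0, k1) = hmm.viterbi_score(prof, cons)
            assert (k0, k1) == (1, prof.M)

    def test_revcomp_score_symmetry(self, small_profile, rng):
        """Scanning a sequence and its reverse complement yields identical
        bit scores with flipped strand flags."""
        for _ in range(10):
            seq = "".join("ACGT"[c] for c in rng.integers(0, 4, 2000))
            fwd_hits = hmm.scan(
                small_profile, [SequenceRecord("s", seq)], evalue_report=50.0
            )
            rev_hits = hmm.scan(
                small_profile, [SequenceRecord("s", revcomp(seq))], evalue_report=50.0
            )
            flip = {"+": "-", "-": "+"}
            a = sorted((round(h.bit_score, 6), h.interval.strand) for h in fwd_hits)
            b = sorted(
                (round(h.bit_score, 6), flip[h.interval.strand]) for h in rev_hits
            )
            assert a == b


class TestCalibration:
    def test_deterministic_under_seed(self, small_refs):
        alns, _ = small_refs
        a = hmm.build_profile(hmm.trim_conserved(alns[("MiSp", "CTD")]), "m")
        b = hmm.build_profile(hmm.trim_conserved(alns[("MiSp", "CTD")]), "m")
        hmm.calibrate(a, n_seqs=100, seq_len=500, seed=7)
        hmm.calibrate(b, n_seqs=100, seq_len=500, seed=7)
        assert (a.gumbel_mu, a.gumbel_lambda) == (b.gumbel_mu, b.gumbel_lambda)

    def test_top_random_hit_has_evalue_near_one(self, small_profile):
        """Mean E of the best hit on fresh calibration-sized random sets."""
        em, logs = small_profile._log2_tables()
        rng = np.random.default_rng(99)
        evals = []
        for _ in range(20):
            best = -np.inf
            for _ in range(30):
                obs = rng.choice(
                    4, size=small_profile.calib_seq_len, p=small_profile.background
                ).astype(np.int8)
                from arachne._viterbi import viterbi_local

                best = max(best, viterbi_local(obs, em, *logs)[0])
            evals.append(
                hmm.evalue(small_profile, best, 30 * small_profile.calib_seq_len)
            )
        assert 0.2 <= np.mean(evals) <= 5.0

    def test_planted_consensus_in_100kbp_background(self):
        """An exact 150-column consensus in 100 kbp scores E < 1e-10."""
        alns, cons = make_reference_set(["MaSp"], n_seqs_per_class=15, seed=5)
        prof = hmm.build_profile(
            hmm.trim_conserved(alns[("MaSp", "NTD")]), "MaSp_NTD", "MaSp", "NTD"
        )
        hmm.calibrate(prof, seed=6)
        rng = np.random.default_rng(8)
        bg = "".join("ACGT"[c] for c in rng.integers(0, 4, 100_000))
        genome = [SequenceRecord("s1", bg[:50_000] + cons[("MaSp", "NTD")] + bg[50_000:])]
        hits = hmm.scan(prof, genome, evalue_report=1.0)
        strong = [h for h in hits if h.evalue < 1e-10]
        assert len(strong) == 1
        assert strong[0].interval.start == pytest.approx(50_000, abs=10)

    def test_uncalibrated_scan_errors(self, small_refs):
        alns, _ = small_refs
        prof = hmm.build_profile(hmm.trim_conserved(alns[("MaSp", "CTD")]), "m")
        with pytest.raises(ValueError, match="calibrated"):
            hmm.scan(prof, [SequenceRecord("s", "ACGT" * 100)])


class TestScan:
    def test_minus_strand_hit_coordinates(self, small_profile, rng):
        cons = small_profile.consensus()
        bg = "".join("ACGT"[c] for c in rng.integers(0, 4, 20_000))
        seq = bg[:8_000] + revcomp(cons) + bg[8_000:]
        hits = hmm.scan(small_profile, [SequenceRecord("s1", seq)], evalue_report=1e-6)
        assert len(hits) == 1
        h = hits[0]
        assert h.interval.strand == "-"
        assert h.interval.start == pytest.approx(8_000, abs=10)
        assert h.interval.end == pytest.approx(8_000 + len(cons), abs=10)

    def test_two_copies_50kbp_apart(self, small_profile, rng):
        cons = small_profile.consensus()
        bg = "".join("ACGT"[c] for c in rng.integers(0, 4, 120_000))
        seq = bg[:30_000] + cons + bg[30_000:80_000] + cons + bg[80_000:]
        hits = hmm.scan(small_profile, [SequenceRecord("s1", seq)], evalue_report=1e-6)
        starts = sorted(h.interval.start for h in hits)
        assert len(hits) == 2
        assert starts[0] == pytest.approx(30_000, abs=10)
        assert starts[1] == pytest.approx(30_000 + len(cons) + 50_000, abs=10)

    def test_empty_genome(self, small_profile):
        assert hmm.scan(small_profile, []) == []

    def test_hit_invariants(self, small_profile, rng):
        seq = "".join("ACGT"[c] for c in rng.integers(0, 4, 30_000))
        for h in hmm.scan(small_profile, [SequenceRecord("s1", seq)], evalue_report=10.0):
            assert 0.0 < h.model_cov <= 1.0
            assert 0 <= h.interval.start < h.interval.end <= 30_000


def test_profile_json_round_trip(tmp_path, small_profile):
    p = tmp_path / "prof.json"
    hmm.profile_to_json(small_profile, p)
    back = hmm.profile_from_json(p)
    assert back.model_id == small_profile.model_id
    assert np.allclose(back.match_emissions, small_profile.match_emissions)
    assert back.gumbel_mu == small_profile.gumbel_mu
    s1 = hmm.viterbi_score(small_profile, small_profile.consensus())
    s2 = hmm.viterbi_score(back, back.consensus())
    assert s1 == s2
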