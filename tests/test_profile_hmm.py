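"""Profile-HMM construction, scoring (against a path-enumeration oracle),
Gumbel calibration and the E-value breakdown detector."""

import numpy as np
import pytest

from metalphylo.models import AMINO_ACIDS
from metalphylo.profile_hmm import (CalibrationError, NoMatchStatesError,
                                    build_profile, calibrate_evalues,
                                    detect_threshold_break, fit_gumbel,
                                    read_profile, score_sequence,
                                    screen_proteomes, write_profile)
from metalphylo.simulate import simulate_background

from oracles import enumerate_profile_paths, random_profile


class TestBuildProfile:
    def test_gapless_alignment_every_column_is_match(self):
        aln = [("a", "ACDEFGHIKL")] * 4
        assert build_profile(aln).match_state_count == 10

    def test_gap_majority_column_is_not_match(self):
        # column 3 has residues in 1 of 4 rows (occupancy 0.25 < 0.5)
        aln = [("a", "AC-EFG"), ("b", "AC-EFG"), ("c", "AC-EFG"),
               ("d", "ACDEFG")]
        p = build_profile(aln)
        assert p.match_state_count == 5
        assert list(p.match_columns) == [1, 2, 4, 5, 6]

    def test_exact_half_occupancy_is_match(self):
        aln = [("a", "AC"), ("b", "A-"), ("c", "AC"), ("d", "A-")]
        assert build_profile(aln).match_state_count == 2

    def test_match_count_below_alignment_length_with_gappy_columns(self):
        """Profiles are shorter than their seed alignments whenever any
        column is gap-majority (as with real superfamily alignments)."""
        rng = np.random.default_rng(0)
        width, n = 60, 8
        rows = []
        for i in range(n):
            row = "".join(rng.choice(list(AMINO_ACIDS), size=width))
            # make a stretch gap-majority
            row = row[:20] + ("-" * 10 if i < 6 else row[20:30]) + row[30:]
            rows.append((f"s{i}", row))
        p = build_profile(rows)
        assert p.match_state_count < width

    def test_all_gap_columns_rejected(self):
        with pytest.raises(NoMatchStatesError):
            build_profile([("a", "--"), ("b", "--"), ("c", "A-")])

    def test_emissions_normalised(self):
        p = build_profile([("a", "ACD"), ("b", "ACD"), ("c", "AVD")])
        np.testing.assert_allclose(p.match_emissions.sum(axis=1), 1.0,
                                   atol=1e-12)


class TestScoringOracle:
    def test_forward_and_viterbi_match_exhaustive_enumeration(self, rng):
        """DP scores equal the brute-force sum/max over every state path of
        the local architecture, to 1e-9 bits."""
        for _ in range(30):
            L = int(rng.integers(1, 5))
            profile = random_profile(rng, L)
            n = int(rng.integers(0, 7))
            seq = "".join(rng.choice(list(AMINO_ACIDS), size=n))
            o_vit, o_fwd = enumerate_profile_paths(profile, seq)
            res = score_sequence(profile, seq)
            assert abs(res.viterbi_bits - o_vit) <= 1e-9
            assert abs(res.forward_bits - o_fwd) <= 1e-9

    def test_forward_at_least_viterbi(self, rng):
        p = random_profile(rng, 4)
        for n in (1, 3, 6):
            seq = "".join(rng.choice(list(AMINO_ACIDS), size=n))
            r = score_sequence(p, seq)
            assert r.forward_bits >= r.viterbi_bits - 1e-12

    def test_empty_sequence_has_defined_score(self, rng):
        r = score_sequence(random_profile(rng, 3), "")
        assert np.isfinite(r.viterbi_bits)
        assert r.viterbi_bits == r.forward_bits

    def test_consensus_recognises_itself(self):
        aln = [("a", "MKVCPCLLAVGHTTWQRNDE")] * 5
        p = build_profile(aln)
        r = score_sequence(p, "MKVCPCLLAVGHTTWQRNDE")
        assert r.viterbi_bits > 0

    def test_consensus_scores_above_decoys(self):
        consensus = "MKVCPCLLAVGHTTWQRNDEFYIKSMPLVA"
        p = build_profile([("a", consensus)] * 5)
        best_decoy = max(
            score_sequence(p, str(d.seq), forward=False).viterbi_bits
            for d in simulate_background(100, (30, 3), seed=1))
        assert score_sequence(p, consensus).viterbi_bits > best_decoy

    def test_ambiguity_codes_score_without_error(self, rng):
        p = random_profile(rng, 3)
        r = score_sequence(p, "AXBZU")
        assert np.isfinite(r.viterbi_bits)

    def test_traceback_span_of_exact_fragment(self):
        aln = [("a", "ACDEFGHIKLMNPQRSTVWY")] * 4
        p = build_profile(aln)
        r = score_sequence(p, "FGHIKL", traceback=True)
        assert (r.qstart, r.qend) == (5, 10)
        assert r.match_residues == "FGHIKL"
        assert r.n_matched == 6


class TestCalibration:
    def test_gumbel_parameter_recovery(self):
        """MLE recovers (mu, lambda) from draws of the assumed law."""
        rng = np.random.default_rng(4)
        draws = rng.gumbel(loc=-5.0, scale=1 / 0.7, size=10_000)
        mu, lam = fit_gumbel(draws)
        assert abs(mu - (-5.0)) <= 0.1
        assert abs(lam - 0.7) <= 0.05

    def test_evalue_at_mu_closed_form(self, rng):
        p = random_profile(rng, 3)
        draws = np.random.default_rng(5).gumbel(-3.0, 1 / 0.6, 2_000)
        calibrate_evalues(p, draws, database_size=1000)
        ev = p.evalue(p.calibration.mu)
        assert ev == pytest.approx(1000 * (1 - np.exp(-1)), rel=1e-6)

    def test_evalues_uniform_under_null(self, rng):
        """Fraction of decoys with E <= x is ~ x/n for small x: E-values of
        null scores are uniform on (0, n]."""
        p = random_profile(rng, 3)
        fit_draws = np.random.default_rng(6).gumbel(-2.0, 1 / 0.8, 10_000)
        calibrate_evalues(p, fit_draws, database_size=10_000)
        test_draws = np.random.default_rng(7).gumbel(-2.0, 1 / 0.8, 10_000)
        evs = p.evalue(test_draws)
        n = evs.size
        for x in (100, 500, 1000):
            frac = np.mean(evs <= x)
            assert frac == pytest.approx(x / n, abs=3 * np.sqrt(
                (x / n) * (1 - x / n) / n))

    def test_degenerate_scores_rejected(self, rng):
        with pytest.raises(CalibrationError):
            fit_gumbel(np.full(1000, 2.5))

    def test_too_few_decoys_rejected(self, rng):
        p = random_profile(rng, 3)
        with pytest.raises(ValueError):
            calibrate_evalues(p, ["ACDEF"] * 10)


class TestThresholdBreak:
    def test_worked_example(self):
        res = detect_threshold_break(
            np.array([1e-40, 1e-35, 1e-30, 1e-8, 1e-5]))
        assert res is not None
        threshold, gap = res
        assert threshold == pytest.approx(1e-19, rel=1e-9)
        assert gap == pytest.approx(22.0)

    def test_no_qualifying_gap(self):
        assert detect_threshold_break(
            np.array([1e-6, 1e-5, 1e-4]), min_gap_orders=3) is None

    def test_all_identical_evalues(self):
        assert detect_threshold_break(np.array([1e-9] * 5)) is None

    def test_tie_resolves_to_smaller_threshold(self):
        # two 5-order gaps; the more stringent (smaller E) midpoint wins
        res = detect_threshold_break(
            np.array([1e-30, 1e-25, 1e-10, 1e-5]), min_gap_orders=4)
        threshold, gap = res
        assert gap == pytest.approx(15.0)

    def test_zero_evalues_clamped_not_fatal(self):
        res = detect_threshold_break(np.array([0.0, 1e-5]),
                                     min_gap_orders=3)
        assert res is not None

    def test_fewer_than_two_hits_rejected(self):
        with pytest.raises(ValueError):
            detect_threshold_break(np.array([1e-10]))


@pytest.fixture(scope="module")
def calibrated():
    consensus = "MKVCPCLLAVGHTTWQRNDEFYIKSMPLVADERW"
    p = build_profile([("a", consensus)] * 6, name="toy")
    calibrate_evalues(p, simulate_background(500, (34, 4), seed=2))
    family = [("f1", consensus), ("f2", consensus[:20] + "A" * 14)]
    decoys = [(f"d{i}", str(r.seq)) for i, r in
              enumerate(simulate_background(5, (34, 4), seed=3))]
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    proteome = [SeqRecord(Seq(s), id=i) for i, s in family + decoys]
    return p, {"gen1": proteome}


class TestScreen:

    def test_infinite_cutoff_reports_everything(self, calibrated):
        p, proteomes = calibrated
        hits = screen_proteomes(p, proteomes, evalue_cutoff=float("inf"))
        assert len(hits) == 7
        assert list(hits.evalue) == sorted(hits.evalue)

    def test_zero_cutoff_reports_nothing(self, calibrated):
        p, proteomes = calibrated
        assert len(screen_proteomes(p, proteomes, evalue_cutoff=0.0)) == 0

    def test_raising_cutoff_never_removes_hits(self, calibrated):
        p, proteomes = calibrated
        lo = set(screen_proteomes(p, proteomes, 1e-3).seq_id)
        hi = set(screen_proteomes(p, proteomes, 10.0).seq_id)
        assert lo <= hi

    def test_unreadable_file_skipped_with_error(self, calibrated, tmp_path):
        p, proteomes = calibrated
        bad = tmp_path / "missing.fasta"
        with pytest.warns(UserWarning):
            hits = screen_proteomes(
                p, {**proteomes, "bad": str(bad)}, float("inf"))
        assert len(hits.attrs["errors"]) == 1
        assert "bad" in hits.attrs["errors"][0]


def test_profile_text_roundtrip(tmp_path, rng):
    p = random_profile(rng, 4)
    calibrate_evalues(p, np.random.default_rng(8).gumbel(-1, 2, 1000),
                      database_size=77)
    path = tmp_path / "p.prof"
    write_profile(p, path)
    q = read_profile(path)
    np.testing.assert_array_equal(q.match_emissions, p.match_emissions)
    np.testing.assert_array_equal(q.t_dd, p.t_dd)
    assert q.calibration.mu == p.calibration.mu
    assert q.calibration.database_size == 77
    seq = "ACDEFG"
    assert score_sequence(q, seq).viterbi_bits == pytest.approx(
        score_sequence(p, seq).viterbi_bits, abs=1e-12)
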