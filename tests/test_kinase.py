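"""Sampling null, exact oracles, and the kinase statistics (z, delta, MEOW)."""

import math

import numpy as np
import pandas as pd
import pytest

import kinomeflow as kf
from kinomeflow.kinase import (
    FLAG_DEGENERATE_NULL,
    FLAG_NO_SUBSTRATE_FC,
    FLAG_UNSTABLE_Z,
    NullDistribution,
)


@pytest.fixture(scope="module")
def kmap6():
    """Five kinases over a 6-peptide background, hand-enumerable."""
    return kf.KinaseSubstrateMap(
        [
            ("KA", "p1"), ("KA", "p2"), ("KA", "p3"),
            ("KB", "p2"), ("KB", "p4"),
            ("KC", "p5"), ("KC", "p6"),
            ("KD", "p1"), ("KD", "p4"), ("KD", "p6"),
            ("KE", "p3"),
        ]
    )


BG6 = frozenset(["p1", "p2", "p3", "p4", "p5", "p6"])


class TestObservedHits:
    def test_intersection_counts_match_hand_enumeration(self, kmap6):
        diff = kf.DifferentialSet("d", frozenset(["p2"]), frozenset(["p4", "p6"]), BG6)
        expected = {"KA": 1, "KB": 2, "KC": 1, "KD": 2, "KE": 0}
        for kin, want in expected.items():
            assert kf.observed_hits(kin, diff, kmap6) == want

    def test_empty_differential_set(self, kmap6):
        diff = kf.DifferentialSet("d", frozenset(), frozenset(), BG6)
        assert kf.observed_hits("KA", diff, kmap6) == 0


class TestSamplingNull:
    def test_saturated_kinase_hits_equal_draw_size(self, kmap6):
        kall = kf.KinaseSubstrateMap([("K", p) for p in sorted(BG6)])
        null = kf.sampling_null("K", 3, kall, BG6, iterations=200, seed=1)
        assert (null.hit_counts == 3).all()
        assert null.sd_hits == 0.0

    def test_kinase_absent_from_background(self, kmap6):
        null = kf.sampling_null("KC", 2, kmap6, ["p1", "p2", "p3", "p4"], iterations=100, seed=2)
        assert null.mean_hits == 0.0

    def test_mean_matches_hypergeometric(self):
        bg = [f"p{i}" for i in range(10)]
        kmap = kf.KinaseSubstrateMap([("K", p) for p in bg[:4]])
        null = kf.sampling_null("K", 3, kmap, bg, iterations=2000, seed=3)
        mean, var = kf.exhaustive_null("K", 3, kmap, bg)
        assert mean == pytest.approx(1.2)
        assert abs(null.mean_hits - mean) <= 3 * math.sqrt(var) / math.sqrt(2000)

    def test_seed_determinism(self, kmap6):
        a = kf.sampling_null("KA", 2, kmap6, BG6, iterations=50, seed=7)
        b = kf.sampling_null("KA", 2, kmap6, BG6, iterations=50, seed=7)
        assert (a.hit_counts == b.hit_counts).all()

    def test_draw_larger_than_background_raises(self, kmap6):
        with pytest.raises(ValueError, match="exceeds"):
            kf.sampling_null("KA", 7, kmap6, BG6, seed=1)


class TestExactNulls:
    @pytest.mark.parametrize(
        "n_subs, n_bg, n_draw, mean, var",
        [
            (4, 10, 3, 1.2, 3 * 0.4 * 0.6 * 7 / 9),
            (0, 10, 3, 0.0, 0.0),
            (10, 10, 3, 3.0, 0.0),
        ],
    )
    def test_closed_form(self, n_subs, n_bg, n_draw, mean, var):
        bg = [f"p{i}" for i in range(n_bg)]
        kmap = kf.KinaseSubstrateMap([("K", p) for p in bg[:n_subs]] or [("K", "zz")])
        got_mean, got_var = kf.exhaustive_null("K", n_draw, kmap, bg)
        assert got_mean == pytest.approx(mean)
        assert got_var == pytest.approx(var)

    def test_enumeration_agrees_with_closed_form(self, kmap6):
        # all C(6,2)=15 subsets enumerated outright
        for kin in kmap6.kinases:
            em, ev = kf.enumerate_null(kin, 2, kmap6, BG6)
            cm, cv = kf.exhaustive_null(kin, 2, kmap6, BG6)
            assert em == pytest.approx(cm, abs=1e-12)
            assert ev == pytest.approx(cv, abs=1e-12)

    def test_sampling_within_monte_carlo_error_of_enumeration(self, kmap6):
        for kin in kmap6.kinases:
            null = kf.sampling_null(kin, 2, kmap6, BG6, iterations=2000, seed=11)
            em, ev = kf.enumerate_null(kin, 2, kmap6, BG6)
            assert abs(null.mean_hits - em) <= max(3 * math.sqrt(ev) / math.sqrt(2000), 1e-12)


def _null(mean, sd, kinase="K"):
    return NullDistribution(kinase, 2000, np.array([]), mean, sd)


class TestKinaseStatistics:
    def test_null_centered_observation(self):
        rec = kf.kinase_statistics(2, _null(2.0, 1.0), [0.5, 0.7])
        assert rec.z == 0.0
        assert rec.delta_confidence == 1.0
        assert rec.meow == pytest.approx(rec.mean_substrate_log2fc)

    def test_arithmetic_example(self):
        rec = kf.kinase_statistics(4, _null(2.0, 1.0), [0.5])
        assert rec.delta_confidence == 2.0
        assert rec.meow == pytest.approx(1.0)

    def test_zero_sd_mismatch_flagged_unstable(self):
        rec = kf.kinase_statistics(3, _null(1.0, 0.0), [0.1])
        assert math.isinf(rec.z) and rec.z > 0
        assert rec.flag == FLAG_UNSTABLE_Z

    def test_empty_null_with_zero_observed_is_degenerate_unity(self):
        rec = kf.kinase_statistics(0, _null(0.0, 0.0), [0.1, -0.1])
        assert rec.delta_confidence == 1.0
        assert rec.z == 0.0
        assert rec.flag == FLAG_DEGENERATE_NULL

    def test_no_substrate_fold_changes_flagged(self):
        rec = kf.kinase_statistics(1, _null(0.5, 0.2), [])
        assert math.isnan(rec.mean_substrate_log2fc)
        assert rec.flag == FLAG_NO_SUBSTRATE_FC

    def test_negating_fold_changes_negates_meow_preserves_z(self):
        lfcs = [0.3, 0.8, -0.1]
        a = kf.kinase_statistics(4, _null(2.0, 0.8), lfcs)
        b = kf.kinase_statistics(4, _null(2.0, 0.8), [-x for x in lfcs])
        assert b.meow == pytest.approx(-a.meow)
        assert b.z == a.z


class TestAnalyzeComparison:
    def test_min_substrates_retention(self, kmap6):
        diff = kf.DifferentialSet("d", frozenset(["p2"]), frozenset(), BG6)
        fc = pd.DataFrame({"peptide_id": sorted(BG6), "log2fc": 0.1, "fc": 1.07})
        stats = kf.analyze_comparison(diff, fc, kmap6, iterations=100, seed=1, min_substrates=3)
        assert set(stats["kinase_id"]) == {"KA", "KD"}  # only kinases with >= 3 substrates

    def test_determinism(self, kmap6):
        diff = kf.DifferentialSet("d", frozenset(["p2", "p4"]), frozenset(), BG6)
        fc = pd.DataFrame({"peptide_id": sorted(BG6), "log2fc": 0.2, "fc": 1.15})
        s1 = kf.analyze_comparison(diff, fc, kmap6, iterations=500, seed=9, min_substrates=2)
        s2 = kf.analyze_comparison(diff, fc, kmap6, iterations=500, seed=9, min_substrates=2)
        pd.testing.assert_frame_equal(s1, s2)


class TestSummarizeKinome:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["kinase_id", "z", "meow"])

    def test_single_record_identity(self):
        out = kf.summarize_kinome(self._frame([("K", 1.5, 0.4)]))
        assert out.loc[0, "median_kinase_statistic"] == 1.5
        assert out.loc[0, "mean_final_score"] == pytest.approx(0.4)

    def test_median_of_three(self):
        out = kf.summarize_kinome(self._frame([("K", -1, 0.0), ("K", 0, 0.0), ("K", 4, 0.0)]))
        assert out.loc[0, "median_kinase_statistic"] == 0.0

    def test_two_comparisons_three_kinases_hand_values(self):
        rows = [
            ("KA", 1.0, 0.5), ("KA", 3.0, -1.5),
            ("KB", -2.0, 0.2), ("KB", 0.0, 0.4),
            ("KC", 0.5, -0.3), ("KC", 0.7, 0.9),
        ]
        out = kf.summarize_kinome(self._frame(rows)).set_index("kinase_id")
        assert out.loc["KA", "color_value"] == pytest.approx(2.0)     # median z
        assert out.loc["KA", "size_value"] == pytest.approx(1.0)      # mean |meow|
        assert out.loc["KB", "color_value"] == pytest.approx(-1.0)
        assert out.loc["KC", "size_value"] == pytest.approx(0.6)
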