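"""Agreement statistics: differences, percent error, t-test, correlation."""

import math

import numpy as np
import pytest

from canalarea import (
    LevelMeasurement,
    approximate_area,
    evaluate_level,
    mean_difference,
    paired_t,
    pearson_r,
    percent_error,
)


class TestMeanDifference:
    def test_identical_series_gives_zero(self):
        x = [250.0, 260.0, 270.0]
        assert mean_difference(x, x) == (0.0, 0.0)

    def test_hand_arithmetic(self):
        # differences {1, 2, 3}: mean 2, sample SD 1
        md, sd = mean_difference([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        assert md == pytest.approx(2.0)
        assert sd == pytest.approx(1.0)

    def test_fewer_than_two_pairs_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            mean_difference([1.0], [0.0])


class TestPercentError:
    @pytest.mark.parametrize(
        "mean_est, mean_man, expected",
        [
            (305.56, 281.78, 8.44),    # ellipse overestimate
            (194.53, 281.78, -30.96),  # triangle underestimate
        ],
    )
    def test_aggregate_reproduces_reference_values(self, mean_est, mean_man, expected):
        assert percent_error(mean_est, mean_man) == pytest.approx(expected, abs=0.005)

    def test_equal_means_give_zero(self):
        assert percent_error(123.4, 123.4) == 0.0

    def test_nonpositive_manual_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            percent_error(100.0, 0.0)

    def test_per_subject_differs_from_aggregate_in_general(self, rng):
        manual = rng.uniform(200, 350, 100)
        est = manual * rng.uniform(0.8, 1.3, 100)
        agg = percent_error(est, manual, mode="aggregate")
        per = percent_error(est, manual, mode="per_subject")
        assert agg != pytest.approx(per, abs=1e-6)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            percent_error(1.0, 1.0, mode="median")

    def test_identity_chain_across_shapes(self, rng):
        """pe_rect = 2*pe_tri + 100 and pe_ell = (pi/4)*pe_rect + 100*(pi/4 - 1)."""
        ipd = rng.uniform(18, 30, 200)
        ap = rng.uniform(10, 22, 200)
        manual = rng.uniform(200, 350, 200)
        pe = {
            s: percent_error(approximate_area(ipd, ap, s), manual)
            for s in ("ellipse", "triangle", "rectangle")
        }
        assert pe["rectangle"] == pytest.approx(2 * pe["triangle"] + 100, rel=1e-12)
        assert pe["ellipse"] == pytest.approx(
            math.pi / 4 * pe["rectangle"] + 100 * (math.pi / 4 - 1), rel=1e-12
        )


class TestPairedT:
    def test_zero_mean_differences(self):
        t, df, p = paired_t([-2.0, -1.0, 1.0, 2.0])
        assert t == 0.0
        assert df == 3
        assert p == pytest.approx(1.0)

    def test_hand_case(self):
        # mean 2, SD 1, n 3 -> t = 2*sqrt(3); p from the df=2 closed form
        # F(t) = 1/2 + t / (2*sqrt(t^2 + 2)) gives p = 0.07418.
        t, df, p = paired_t([1.0, 2.0, 3.0])
        assert t == pytest.approx(2 * math.sqrt(3), rel=1e-12)
        assert df == 2
        assert p == pytest.approx(0.07418, abs=1e-4)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            paired_t([2.0, 2.0, 2.0])


class TestPearson:
    def test_perfect_positive(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pearson_r(x, [2 * v for v in x]) == pytest.approx(1.0)

    def test_perfect_negative(self):
        assert pearson_r([1.0, 2.0, 3.0], [3.0, 2.0, 1.0]) == pytest.approx(-1.0)

    def test_affine_invariance(self, rng):
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        assert pearson_r(3.7 * x + 11, y) == pytest.approx(pearson_r(x, y), abs=1e-13)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            pearson_r([1.0, 2.0], [3.0, 4.0])
        with pytest.raises(ValueError, match="zero-variance"):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestEvaluateLevel:
    @staticmethod
    def _measurements(rng, n=40, level="L2"):
        ipd = rng.uniform(18, 30, n)
        ap = rng.uniform(10, 22, n)
        manual = 0.72 * ipd * ap + rng.normal(0, 20, n)
        manual = np.clip(manual, 50, None)
        return [
            LevelMeasurement(f"P{i}", level, ipd[i], ap[i], manual[i])
            for i in range(n)
        ]

    def test_matches_brute_force_recomputation(self, rng):
        """Every field agrees with a plain-formula recomputation from raw pairs."""
        ms = self._measurements(rng)
        res = evaluate_level(ms, "ellipse")
        ipd = np.array([m.ipd for m in ms])
        ap = np.array([m.ap for m in ms])
        manual = np.array([m.manual_area for m in ms])
        est = math.pi / 4 * ipd * ap
        d = est - manual
        n = len(ms)
        assert res.n == n
        assert res.mean_manual == pytest.approx(manual.mean(), rel=1e-14)
        assert res.sd_manual == pytest.approx(manual.std(ddof=1), rel=1e-14)
        assert res.mean_estimate == pytest.approx(est.mean(), rel=1e-14)
        assert res.mean_difference == pytest.approx(d.mean(), rel=1e-12)
        assert res.sd_difference == pytest.approx(d.std(ddof=1), rel=1e-12)
        t_expected = d.mean() / (d.std(ddof=1) / math.sqrt(n))
        assert res.t_statistic == pytest.approx(t_expected, rel=1e-12)
        assert res.percent_error == pytest.approx(
            100 * (est.mean() - manual.mean()) / manual.mean(), rel=1e-12
        )
        r_num = np.sum((est - est.mean()) * (manual - manual.mean()))
        r_den = math.sqrt(np.sum((est - est.mean()) ** 2) * np.sum((manual - manual.mean()) ** 2))
        assert res.pearson_r == pytest.approx(r_num / r_den, abs=1e-12)

    def test_result_internal_invariants(self, rng):
        res = evaluate_level(self._measurements(rng), "rectangle")
        assert res.mean_difference == pytest.approx(
            res.mean_estimate - res.mean_manual, rel=1e-12
        )
        assert math.copysign(1, res.t_statistic) == math.copysign(1, res.mean_difference)

    def test_mixed_levels_rejected(self, rng):
        ms = self._measurements(rng, level="L1") + self._measurements(rng, level="L2")
        with pytest.raises(ValueError, match="multiple levels"):
            evaluate_level(ms, "ellipse")

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no measurements"):
            evaluate_level([], "ellipse")

    def test_missing_manual_area_rejected(self):
        ms = [LevelMeasurement("P1", "L1", 24.0, 16.0), LevelMeasurement("P2", "L1", 25.0, 17.0)]
        with pytest.raises(ValueError, match="manual_area"):
            evaluate_level(ms, "ellipse")

    def test_zero_variance_cohort_rejected(self):
        ms = [
            LevelMeasurement(f"P{i}", "L1", 24.0, 16.0, 24.0 * 16.0 * 0.7)
            for i in range(5)
        ]
        with pytest.raises(ValueError):
            evaluate_level(ms, "ellipse")
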