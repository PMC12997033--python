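"""Post-hoc recalibration: scaling, isotonic, conformal, Venn-ABERS."""

import numpy as np
import pytest
from scipy.special import expit, logit

from uqeval import (
    BinaryPredictionSet,
    CalibrationSplit,
    ClassificationSimConfig,
    ConformalConfig,
    GaussianPredictionSet,
    QuantilePredictionSet,
    RegressionSimConfig,
    ValidationError,
    conformal_quantile,
    conformalize_gaussian,
    conformalize_quantiles,
    fit_isotonic_cls,
    fit_isotonic_reg,
    fit_temperature_cls,
    fit_variance_scale_reg,
    gaussian_to_quantiles,
    simulate_classification,
    simulate_regression,
    venn_abers_predict,
)
from uqeval.metrics_cls import nll_cls
from uqeval.metrics_reg import nll_gaussian


def _cls_split(T_true, n_calib=20_000, n_test=2_000, seed=0):
    calib = simulate_classification(
        ClassificationSimConfig(n=n_calib, T_true=T_true, seed=seed)
    )
    test = simulate_classification(
        ClassificationSimConfig(n=n_test, T_true=T_true, seed=seed + 1)
    )
    return CalibrationSplit(calib, test)


class TestTemperatureScaling:
    @pytest.mark.parametrize("T_true", [0.5, 2.0])
    def test_recovers_distortion_temperature(self, T_true):
        T, _ = fit_temperature_cls(_cls_split(T_true))
        assert T == pytest.approx(T_true, abs=0.1 * (T_true / 2))

    def test_calibrated_data_gives_unit_temperature(self):
        T, _ = fit_temperature_cls(_cls_split(1.0))
        assert T == pytest.approx(1.0, abs=0.05)

    def test_identity_temperature_preserves_probabilities(self):
        test = BinaryPredictionSet([1, 0, 1], [0.7, 0.3, 0.9])
        z = logit(np.asarray(test.p1))
        np.testing.assert_allclose(expit(z / 1.0), test.p1, atol=1e-12)

    def test_single_class_calibration_rejected(self):
        calib = BinaryPredictionSet(np.ones(50), np.linspace(0.1, 0.9, 50))
        test = BinaryPredictionSet([0, 1], [0.5, 0.5])
        with pytest.raises(ValidationError, match="both classes"):
            fit_temperature_cls(CalibrationSplit(calib, test))

    def test_never_increases_calibration_nll(self):
        split = _cls_split(0.5, n_calib=5_000)
        T, _ = fit_temperature_cls(split)
        _, recal_calib = fit_temperature_cls(
            CalibrationSplit(split.calib, split.calib)
        )
        assert nll_cls(recal_calib) <= nll_cls(split.calib) + 1e-9


class TestVarianceScaling:
    def test_recovers_overconfidence_factor(self):
        calib = simulate_regression(RegressionSimConfig(n=50_000, c=0.5, seed=3))
        test = simulate_regression(RegressionSimConfig(n=500, c=0.5, seed=4))
        s, out = fit_variance_scale_reg(CalibrationSplit(calib, test))
        assert s == pytest.approx(4.0, abs=0.15)
        np.testing.assert_allclose(out.var, s * test.var, atol=1e-12)
        np.testing.assert_array_equal(out.mu, test.mu)

    def test_calibrated_data_gives_unit_scale(self):
        calib = simulate_regression(RegressionSimConfig(n=50_000, seed=5))
        test = simulate_regression(RegressionSimConfig(n=500, seed=6))
        s, _ = fit_variance_scale_reg(CalibrationSplit(calib, test))
        assert s == pytest.approx(1.0, abs=0.05)

    def test_degenerate_residuals_clamped_with_warning(self):
        y = np.linspace(0, 1, 30)
        calib = GaussianPredictionSet(y, y.copy(), np.ones(30))
        test = GaussianPredictionSet([0.5], [0.4], [1.0])
        with pytest.warns(RuntimeWarning, match="clamped"):
            s, _ = fit_variance_scale_reg(CalibrationSplit(calib, test))
        assert s == pytest.approx(1e-6)

    def test_never_increases_calibration_nll(self):
        calib = simulate_regression(RegressionSimConfig(n=5_000, c=0.4, seed=8))
        s, recal = fit_variance_scale_reg(CalibrationSplit(calib, calib))
        assert nll_gaussian(recal) <= nll_gaussian(calib) + 1e-9


class TestIsotonicClassification:
    def test_hand_pav_example(self):
        calib = BinaryPredictionSet([0, 0, 1, 1], [0.2, 0.3, 0.6, 0.9])
        test = BinaryPredictionSet([1], [0.7])
        mapper, out = fit_isotonic_cls(CalibrationSplit(calib, test))
        np.testing.assert_allclose(
            mapper(np.array([0.2, 0.3, 0.6, 0.9])), [1e-6, 1e-6, 1 - 1e-6, 1 - 1e-6]
        )
        assert out.p1[0] == pytest.approx(1 - 1e-6)

    def test_anticalibrated_pools_to_constant_half(self):
        # labels exactly opposite to score order -> single pooled block at 0.5
        calib = BinaryPredictionSet([1, 1, 0, 0], [0.1, 0.2, 0.8, 0.9])
        test = BinaryPredictionSet([1, 0], [0.15, 0.85])
        mapper, _ = fit_isotonic_cls(CalibrationSplit(calib, test))
        np.testing.assert_allclose(mapper(np.array([0.1, 0.5, 0.9])), 0.5)

    def test_fixed_point_when_already_frequency_matched(self):
        p = np.repeat([0.25, 0.75], 4)
        y = np.array([0, 0, 0, 1, 1, 1, 1, 0], dtype=float)
        calib = BinaryPredictionSet(y, p)
        test = BinaryPredictionSet([1, 0], [0.25, 0.75])
        _, out = fit_isotonic_cls(CalibrationSplit(calib, test))
        np.testing.assert_allclose(out.p1, [0.25, 0.75], atol=1e-9)

    def test_output_monotone_in_input(self):
        split = _cls_split(0.5, n_calib=2_000, n_test=10)
        mapper, _ = fit_isotonic_cls(split)
        grid = np.linspace(0, 1, 201)
        assert (np.diff(mapper(grid)) >= -1e-12).all()


class TestIsotonicRegression:
    def test_calibrated_data_nearly_unchanged(self):
        calib = simulate_regression(RegressionSimConfig(n=50_000, seed=21))
        test = simulate_regression(RegressionSimConfig(n=2_000, seed=22))
        out = fit_isotonic_reg(CalibrationSplit(calib, test))
        rms_change = np.sqrt(np.mean((out.sigma / test.sigma - 1) ** 2))
        assert rms_change < 0.05

    def test_overconfident_sigmas_doubled(self):
        calib = simulate_regression(RegressionSimConfig(n=50_000, c=0.5, seed=23))
        test = simulate_regression(RegressionSimConfig(n=2_000, c=0.5, seed=24))
        out = fit_isotonic_reg(CalibrationSplit(calib, test))
        ratio_rms = np.sqrt(np.mean((out.sigma / test.sigma) ** 2))
        assert ratio_rms == pytest.approx(2.0, rel=0.1)

    def test_small_calibration_set_rejected(self):
        calib = simulate_regression(RegressionSimConfig(n=10, seed=25))
        test = simulate_regression(RegressionSimConfig(n=10, seed=26))
        with pytest.raises(ValidationError, match=">= 20"):
            fit_isotonic_reg(CalibrationSplit(calib, test))

    def test_constant_pit_warns(self):
        y = np.full(30, 1.0)
        calib = GaussianPredictionSet(y, y.copy(), np.ones(30))
        test = simulate_regression(RegressionSimConfig(n=10, seed=27))
        with pytest.warns(RuntimeWarning):
            fit_isotonic_reg(CalibrationSplit(calib, test))


class TestConformal:
    def test_order_statistic_rule_by_hand(self):
        assert conformal_quantile(np.array([1.0, 2.0, 3.0, 4.0]), alpha=0.2) == 4.0

    def test_alpha_near_one_gives_smallest_score(self):
        assert conformal_quantile(np.array([3.0, 1.0, 2.0]), alpha=0.99) == 1.0

    def test_too_small_calibration_set_rejected(self):
        with pytest.raises(ValidationError, match="too small"):
            conformal_quantile(np.array([1.0, 2.0]), alpha=0.05)

    def test_cmap_interval_shape(self):
        calib = simulate_regression(RegressionSimConfig(n=200, seed=31))
        test = simulate_regression(RegressionSimConfig(n=50, seed=32))
        ips = conformalize_gaussian(
            CalibrationSplit(calib, test), ConformalConfig(alpha=0.1)
        )
        assert ips.nominal_level == pytest.approx(0.9)
        np.testing.assert_allclose(
            ips.hi - ips.lo, 2 * (ips.hi - test.mu), atol=1e-9
        )  # symmetric about mu

    def test_cqr_negative_correction_shrinks_conservative_intervals(self):
        # every calib y is inside its interval with slack >= 1 -> q_hat <= -1
        y = np.array([0.0, 0.1, -0.1, 0.2, -0.2])
        q = np.column_stack([y - 2.0, y + 2.0])
        calib = QuantilePredictionSet(y, (0.1587, 0.8413), q)
        test = QuantilePredictionSet([0.0], (0.1587, 0.8413), [[-2.0, 2.0]])
        ips = conformalize_quantiles(
            CalibrationSplit(calib, test), ConformalConfig(alpha=0.4, score="cqr")
        )
        assert ips.hi[0] - ips.lo[0] < 4.0

    def test_zero_correction_keeps_intervals(self):
        # symmetric scores around 0 chosen so q_hat lands exactly on 0
        y = np.array([-1.0, 0.0, 1.0, 2.0])
        q = np.column_stack([y - np.array([1.0, 2.0, 0.0, 3.0]), y + np.array([2.0, 1.0, 0.0, 3.0])])
        calib = QuantilePredictionSet(np.sort(y), (0.1587, 0.8413), np.sort(q, axis=0))
        scores = np.maximum(calib.q[:, 0] - calib.y_true, calib.y_true - calib.q[:, 1])
        alpha = 0.2
        q_hat = conformal_quantile(scores, alpha)
        test = QuantilePredictionSet([0.0], (0.1587, 0.8413), [[-1.0, 1.0]])
        ips = conformalize_quantiles(
            CalibrationSplit(calib, test), ConformalConfig(alpha=alpha, score="cqr")
        )
        assert ips.lo[0] == pytest.approx(-1.0 - q_hat)
        assert ips.hi[0] == pytest.approx(1.0 + q_hat)

    @pytest.mark.parametrize("method", ["cmap", "cqr"])
    def test_exchangeable_coverage_one_split(self, method):
        """Marginal coverage close to 1 - alpha on a single exchangeable split
        (the full 500-replicate guarantee check lives in the acceptance suite)."""
        alpha = 0.1
        rng = np.random.default_rng(77)
        cov = []
        for rep in range(20):
            calib = simulate_regression(RegressionSimConfig(n=1000, seed=int(rng.integers(2**31))))
            test = simulate_regression(RegressionSimConfig(n=1000, seed=int(rng.integers(2**31))))
            if method == "cmap":
                ips = conformalize_gaussian(
                    CalibrationSplit(calib, test), ConformalConfig(alpha=alpha)
                )
            else:
                split = CalibrationSplit(
                    gaussian_to_quantiles(calib), gaussian_to_quantiles(test)
                )
                ips = conformalize_quantiles(split, ConformalConfig(alpha=alpha, score="cqr"))
            cov.append(((ips.y_true >= ips.lo) & (ips.y_true <= ips.hi)).mean())
        assert np.mean(cov) == pytest.approx(0.9, abs=0.02)


class TestVennAbers:
    def test_perfect_separation_upper_estimate(self):
        # all class-0 scores below all class-1 scores; test score above all
        calib = BinaryPredictionSet(
            [0, 0, 0, 1, 1, 1], [0.1, 0.2, 0.3, 0.7, 0.8, 0.9]
        )
        test = BinaryPredictionSet([1], [0.95])
        res = venn_abers_predict(CalibrationSplit(calib, test))
        n1 = 3
        assert res.p1[0] == pytest.approx(1.0)
        assert res.p0[0] == pytest.approx(n1 / (n1 + 1))

    def test_constant_scores_give_pooled_half(self):
        n = 40
        y = np.tile([0.0, 1.0], n // 2)
        calib = BinaryPredictionSet(y, np.full(n, 0.5))
        test = BinaryPredictionSet([1, 0], [0.5, 0.5])
        res = venn_abers_predict(CalibrationSplit(calib, test))
        np.testing.assert_allclose(res.p_merged, 0.5, atol=1.5 / n)

    def test_interval_order_and_merged_range_on_random_inputs(self):
        split = _cls_split(0.7, n_calib=300, n_test=40, seed=9)
        res = venn_abers_predict(split)
        assert (res.p0 <= res.p1 + 1e-12).all()
        assert ((res.p_merged >= 0) & (res.p_merged <= 1)).all()

    def test_empty_or_single_class_calibration_rejected(self):
        calib = BinaryPredictionSet(np.zeros(5), np.linspace(0.1, 0.5, 5))
        test = BinaryPredictionSet([1], [0.5])
        with pytest.raises(ValidationError, match="both classes"):
            venn_abers_predict(CalibrationSplit(calib, test))
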