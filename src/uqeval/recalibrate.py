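"""Post-hoc recalibration and conformal prediction.

Every method here follows the same protocol: fit a transformation on a
held-out calibration split, then apply it to test predictions. Implemented
methods:

* temperature scaling of classification probabilities (scalar ``T`` dividing
  the logit, fitted by NLL minimization),
* variance scaling of regression Gaussians (scalar ``s`` multiplying the
  variance; closed-form Gaussian-NLL minimizer),
* isotonic regression for classification (pool-adjacent-violators map from
  score to empirical frequency) and for regression (quantile recalibration
  through the empirical CDF of calibration PIT values),
* split conformal prediction for Gaussian outputs (standardized absolute
  residual score) and for quantile pairs (CQR score), both using the
  finite-sample-valid ceil((n+1)(1-alpha)) order statistic,
* Venn-ABERS probability intervals from a pair of label-augmented isotonic
  fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import expit, logit
from scipy.stats import norm
from sklearn.isotonic import IsotonicRegression

from .convert import quantiles_to_gaussian
from .core import (
    BinaryPredictionSet,
    GaussianPredictionSet,
    IntervalPredictionSet,
    QuantilePredictionSet,
    ValidationError,
)

__all__ = [
    "PROB_EPS",
    "CalibrationSplit",
    "ConformalConfig",
    "conformal_quantile",
    "fit_temperature_cls",
    "fit_variance_scale_reg",
    "fit_isotonic_cls",
    "fit_isotonic_reg",
    "conformalize_gaussian",
    "conformalize_quantiles",
    "venn_abers_predict",
    "VennAbersResult",
]

#: Probability clipping bound applied before any log; keeps NLL finite with
#: negligible bias.
PROB_EPS = 1e-6

#: Variance-scale floor used when calibration residuals are degenerate.
SCALE_FLOOR = 1e-6


@dataclass
class CalibrationSplit:
    """A (calibration, test) pair of prediction sets of the same type.

    Disjointness is the caller's responsibility — these are meant to be a
    held-out calibration split and the final test split.
    """

    calib: object
    test: object

    def __post_init__(self) -> None:
        self.calib.validate()
        self.test.validate()
        if type(self.calib) is not type(self.test):
            raise ValidationError(
                "calibration and test sets must be the same prediction-set type"
            )


@dataclass
class ConformalConfig:
    """alpha : target miscoverage in (0,1); score : nonconformity score family."""

    alpha: float = 1 - (2 * norm.cdf(1) - 1)  # 1-sigma central band
    score: str = "absolute-standardised"  # or "cqr"

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must lie in (0,1)")


def _clip_prob(p: np.ndarray) -> np.ndarray:
    return np.clip(p, PROB_EPS, 1 - PROB_EPS)


def _binary_nll(p: np.ndarray, y: np.ndarray) -> float:
    p = _clip_prob(p)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log1p(-p)))


def _require_both_classes(y: np.ndarray, what: str) -> None:
    if len(np.unique(y)) < 2:
        raise ValidationError(f"{what} requires both classes in the calibration set")


# ---------------------------------------------------------------------------
# Temperature / variance scaling
# ---------------------------------------------------------------------------


def fit_temperature_cls(
    split: CalibrationSplit,
) -> tuple[float, BinaryPredictionSet]:
    """Fit a scalar temperature on the calibration split, apply to test.

    ``T`` minimizes the mean negative log-likelihood of the calibration
    labels under ``p(T) = logistic(logit(p1) / T)``; bounded scalar search on
    ``T in [0.05, 20]``. Returns the fitted temperature and the transformed
    test set.
    """
    calib, test = split.calib, split.test
    _require_both_classes(calib.y_true, "temperature scaling")
    z = logit(_clip_prob(calib.p1))
    y = calib.y_true

    res = minimize_scalar(
        lambda T: _binary_nll(expit(z / T), y),
        bounds=(0.05, 20.0),
        method="bounded",
        options={"xatol": 1e-6},
    )
    T = float(res.x)
    p_test = expit(logit(_clip_prob(test.p1)) / T)
    out = BinaryPredictionSet(test.y_true, p_test, test.logit_mu, test.logit_var)
    return T, out.validate()


def fit_variance_scale_reg(
    split: CalibrationSplit,
) -> tuple[float, GaussianPredictionSet]:
    """Fit a scalar variance multiplier on the calibration split, apply to test.

    The Gaussian-NLL minimizer over ``var' = s * var`` has the closed form
    ``s = mean((y - mu)^2 / var)``; degenerate (all-zero) residuals clamp
    ``s`` to a small floor with a warning. Test means are unchanged.
    """
    calib, test = split.calib, split.test
    if len(calib) < 2:
        raise ValidationError("variance scaling requires a calibration set of size >= 2")
    s = float(np.mean((calib.y_true - calib.mu) ** 2 / calib.var))
    if s < SCALE_FLOOR:
        warnings.warn(
            f"degenerate calibration residuals: variance scale clamped to {SCALE_FLOOR}",
            RuntimeWarning,
            stacklevel=2,
        )
        s = SCALE_FLOOR
    out = GaussianPredictionSet(test.y_true, test.mu, s * test.var)
    return s, out.validate()


# ---------------------------------------------------------------------------
# Isotonic regression
# ---------------------------------------------------------------------------


def _step_function(x_knots: np.ndarray, y_knots: np.ndarray) -> Callable:
    """Right-continuous piecewise-constant extension of isotonic knots."""

    def f(t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(x_knots, t, side="right") - 1
        idx = np.clip(idx, 0, len(x_knots) - 1)
        return y_knots[idx]

    return f


def fit_isotonic_cls(
    split: CalibrationSplit,
) -> tuple[Callable, BinaryPredictionSet]:
    """Isotonic (nondecreasing least-squares) recalibration of probabilities.

    Fits label on ``p1`` over the calibration split by pool-adjacent-
    violators; test probabilities are mapped through the fitted step function
    (piecewise-constant, right-continuous between knots) and clipped to
    ``[PROB_EPS, 1 - PROB_EPS]``. Returns the map and the transformed test set.
    """
    calib, test = split.calib, split.test
    _require_both_classes(calib.y_true, "isotonic regression")
    iso = IsotonicRegression(y_min=0.0, y_max=1.0, out_of_bounds="clip")
    iso.fit(calib.p1, calib.y_true)
    step = _step_function(iso.X_thresholds_, iso.y_thresholds_)

    def mapper(p):
        return _clip_prob(step(p))

    out = BinaryPredictionSet(
        test.y_true, mapper(test.p1), test.logit_mu, test.logit_var
    )
    return mapper, out.validate()


def fit_isotonic_reg(split: CalibrationSplit) -> GaussianPredictionSet:
    """Quantile (PIT) recalibration of regression Gaussians.

    The empirical CDF of the calibration PIT values, fitted isotonically
    against nominal level, defines a monotone map ``R``. For each target
    level tau in the 1-sigma pair (0.1587, 0.8413), the recalibrated quantile
    of a test predictive CDF is its quantile at the adjusted level
    ``R^{-1}(tau)``; the output Gaussian is refit through that quantile pair.
    """
    calib, test = split.calib, split.test
    if len(calib) < 20:
        raise ValidationError(
            "isotonic regression recalibration requires >= 20 calibration examples"
        )
    pits = norm.cdf((calib.y_true - calib.mu) / calib.sigma)
    if np.ptp(pits) < 1e-12:
        warnings.warn(
            "degenerate calibration PIT spread: recalibration map is constant",
            RuntimeWarning,
            stacklevel=2,
        )
    order = np.argsort(pits)
    xs = pits[order]
    ys = np.arange(1, len(xs) + 1) / (len(xs) + 1)  # empirical CDF, open at 0/1
    iso = IsotonicRegression(y_min=0.0, y_max=1.0, out_of_bounds="clip")
    fitted = iso.fit_transform(xs, ys)

    def inverse_map(tau: float) -> float:
        # smallest nominal level p with R(p) >= tau, by monotone interpolation
        return float(
            np.interp(tau, fitted, xs, left=xs[0], right=xs[-1])
        )

    lo_l, hi_l = 0.1587, 0.8413
    adj_lo = np.clip(inverse_map(lo_l), PROB_EPS, 1 - PROB_EPS)
    adj_hi = np.clip(inverse_map(hi_l), PROB_EPS, 1 - PROB_EPS)
    if adj_hi <= adj_lo:
        warnings.warn(
            "recalibration map collapsed the quantile pair; falling back to input spread",
            RuntimeWarning,
            stacklevel=2,
        )
        return GaussianPredictionSet(test.y_true, test.mu, test.var).validate()
    q_lo = test.mu + test.sigma * norm.ppf(adj_lo)
    q_hi = test.mu + test.sigma * norm.ppf(adj_hi)
    qps = QuantilePredictionSet(test.y_true, (lo_l, hi_l), np.column_stack([q_lo, q_hi]))
    return quantiles_to_gaussian(qps)


# ---------------------------------------------------------------------------
# Split conformal prediction
# ---------------------------------------------------------------------------


def conformal_quantile(scores: np.ndarray, alpha: float) -> float:
    """Finite-sample conformal quantile of calibration scores.

    Returns the ``ceil((n+1)(1-alpha))``-th smallest score; raises when the
    calibration set is too small for the requested coverage.
    """
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    rank = int(np.ceil((n + 1) * (1 - alpha)))
    if rank > n:
        raise ValidationError(
            f"calibration set too small for requested coverage "
            f"(need rank {rank} of {n} scores)"
        )
    return float(np.sort(scores)[max(rank, 1) - 1])


def conformalize_gaussian(
    split: CalibrationSplit, cfg: ConformalConfig
) -> IntervalPredictionSet:
    """Split conformal intervals from Gaussian outputs (conformalized MAP).

    Nonconformity score ``|y - mu| / sigma`` on the calibration split; test
    intervals ``mu +/- q_hat * sigma`` at nominal level ``1 - alpha``.
    """
    calib, test = split.calib, split.test
    scores = np.abs(calib.y_true - calib.mu) / calib.sigma
    q_hat = conformal_quantile(scores, cfg.alpha)
    half = q_hat * test.sigma
    return IntervalPredictionSet(
        test.y_true, test.mu - half, test.mu + half, 1 - cfg.alpha
    ).validate()


def conformalize_quantiles(
    split: CalibrationSplit, cfg: ConformalConfig
) -> IntervalPredictionSet:
    """Conformalized quantile regression (CQR) intervals.

    Score ``max(q_lo - y, y - q_hi)`` on the calibration split; test
    intervals ``[q_lo - q_hat, q_hi + q_hat]``. Negative ``q_hat`` shrinks
    intervals that were uniformly conservative on calibration data.
    """
    calib, test = split.calib, split.test
    if len(calib.levels) != 2:
        raise ValidationError("CQR requires exactly two quantile levels")
    lo_l, hi_l = calib.levels
    if abs((lo_l + hi_l) - 1.0) > 1e-6:
        raise ValidationError("CQR requires symmetric quantile levels")
    scores = np.maximum(calib.q[:, 0] - calib.y_true, calib.y_true - calib.q[:, 1])
    q_hat = conformal_quantile(scores, cfg.alpha)
    return IntervalPredictionSet(
        test.y_true, test.q[:, 0] - q_hat, test.q[:, 1] + q_hat, 1 - cfg.alpha
    ).validate()


# ---------------------------------------------------------------------------
# Venn-ABERS
# ---------------------------------------------------------------------------


@dataclass
class VennAbersResult:
    """Per-test-example probability interval (p0, p1) and merged probability."""

    p0: np.ndarray
    p1: np.ndarray
    p_merged: np.ndarray

    def as_prediction_set(self, y_true: np.ndarray) -> BinaryPredictionSet:
        return BinaryPredictionSet(y_true, self.p_merged).validate()


def venn_abers_predict(
    split: CalibrationSplit, score: str = "p1"
) -> VennAbersResult:
    """Inductive Venn-ABERS probability intervals.

    For each test example with score ``s``, fit an isotonic regression on the
    calibration (score, label) pairs augmented with ``(s, 0)`` to get
    ``p0(s)``, and augmented with ``(s, 1)`` to get ``p1(s)``. The pair
    brackets the class-1 probability; the merged point estimate is
    ``p1 / (1 - p0 + p1)`` (minimax log-loss merge). ``score`` selects the
    underlying scalar: ``"p1"`` or ``"logit"`` (logit-scale mean).
    """
    calib, test = split.calib, split.test
    if len(calib) < 1:
        raise ValidationError("Venn-ABERS requires a nonempty calibration set")
    _require_both_classes(calib.y_true, "Venn-ABERS")

    def get_scores(ps: BinaryPredictionSet) -> np.ndarray:
        if score == "p1":
            return np.asarray(ps.p1, dtype=float)
        if score == "logit":
            if not ps.has_logits:
                raise ValidationError("score='logit' requires logit fields")
            return np.asarray(ps.logit_mu, dtype=float)
        raise ValidationError(f"unknown Venn-ABERS score {score!r}")

    s_cal = get_scores(calib)
    y_cal = calib.y_true
    s_test = get_scores(test)

    p0 = np.empty(len(s_test))
    p1 = np.empty(len(s_test))
    for i, s in enumerate(s_test):
        for label, out in ((0.0, p0), (1.0, p1)):
            iso = IsotonicRegression(y_min=0.0, y_max=1.0, out_of_bounds="clip")
            iso.fit(np.append(s_cal, s), np.append(y_cal, label))
            out[i] = iso.predict([s])[0]
    merged = p1 / (1 - p0 + p1)
    return VennAbersResult(p0=p0, p1=p1, p_merged=merged)
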