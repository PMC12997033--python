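"""Conversions among predictive output types.

Different uncertainty-quantification techniques emit different output types
(Gaussian parameters, quantile pairs, central intervals); the conversions
here let any technique be scored by any metric under a shared Gaussian
assumption. The point prediction of an interval or quantile pair is its
midpoint — not a median — so converted means are comparable across
techniques; the spread is recovered from the exact standard-normal z-score
of the stated level (0.8413 maps to z ≈ 0.99982, not snapped to 1).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.stats import norm

from .core import (
    GaussianPredictionSet,
    IntervalPredictionSet,
    QuantilePredictionSet,
    ValidationError,
)

__all__ = [
    "quantiles_to_gaussian",
    "gaussian_to_quantiles",
    "gaussian_to_interval",
    "interval_to_sigma",
    "pit_values",
    "n_sigma_level",
]


def n_sigma_level(n_sigma: float) -> float:
    """Central coverage of a +/- n_sigma Gaussian interval: 2*Phi(n_sigma) - 1."""
    if n_sigma <= 0:
        raise ValidationError("n_sigma must be positive")
    return float(2 * norm.cdf(n_sigma) - 1)


def quantiles_to_gaussian(qps: QuantilePredictionSet) -> GaussianPredictionSet:
    """Fit a Gaussian through a symmetric quantile pair.

    Requires exactly two levels ``(l, 1-l)``. The mean is the midpoint of the
    two quantiles and ``sigma = (q_hi - q_lo) / (2 z)`` with ``z`` the
    standard-normal quantile of the upper level. Asymmetric pairs are
    rejected rather than heuristically symmetrized.
    """
    qps.validate()
    if len(qps.levels) != 2:
        raise ValidationError("quantiles_to_gaussian requires exactly two levels")
    lo_l, hi_l = qps.levels
    if abs((lo_l + hi_l) - 1.0) > 1e-6:
        raise ValidationError(
            f"levels ({lo_l}, {hi_l}) are not symmetric about 0.5"
        )
    q_lo, q_hi = qps.q[:, 0], qps.q[:, 1]
    degenerate = q_hi == q_lo
    if degenerate.any():
        idx = int(np.flatnonzero(degenerate)[0])
        raise ValidationError(f"zero-width quantile pair at example {idx}")
    z = norm.ppf(hi_l)
    mu = 0.5 * (q_lo + q_hi)
    sigma = (q_hi - q_lo) / (2 * z)
    return GaussianPredictionSet(qps.y_true, mu, sigma**2).validate()


def gaussian_to_quantiles(
    gps: GaussianPredictionSet, levels: Sequence[float] = (0.1587, 0.8413)
) -> QuantilePredictionSet:
    """Extract predictive quantiles ``mu + sigma * Phi^{-1}(level)`` from a
    Gaussian set. Left inverse of :func:`quantiles_to_gaussian` for symmetric
    level pairs."""
    gps.validate()
    z = norm.ppf(np.asarray(levels, dtype=float))
    q = gps.mu[:, None] + gps.sigma[:, None] * z[None, :]
    return QuantilePredictionSet(gps.y_true, tuple(levels), q).validate()


def gaussian_to_interval(
    gps: GaussianPredictionSet, n_sigma: float = 1
) -> IntervalPredictionSet:
    """Central interval ``mu +/- n_sigma * sigma`` at nominal level 2*Phi(n_sigma)-1."""
    gps.validate()
    level = n_sigma_level(n_sigma)
    sigma = gps.sigma
    return IntervalPredictionSet(
        gps.y_true, gps.mu - n_sigma * sigma, gps.mu + n_sigma * sigma, level
    ).validate()


def interval_to_sigma(ips: IntervalPredictionSet) -> GaussianPredictionSet:
    """Recover Gaussian parameters from a central interval.

    ``mu`` is the midpoint and ``sigma = halfwidth / z`` with ``z`` the
    standard-normal quantile of ``(1 + nominal_level) / 2``. Exact inverse
    of :func:`gaussian_to_interval` at the same level.
    """
    ips.validate()
    degenerate = ips.hi == ips.lo
    if degenerate.any():
        idx = int(np.flatnonzero(degenerate)[0])
        raise ValidationError(f"zero-width interval at example {idx}")
    z = norm.ppf((1 + ips.nominal_level) / 2)
    mu = 0.5 * (ips.lo + ips.hi)
    sigma = 0.5 * (ips.hi - ips.lo) / z
    return GaussianPredictionSet(ips.y_true, mu, sigma**2).validate()


def pit_values(gps: GaussianPredictionSet) -> np.ndarray:
    """Probability integral transform: ``Phi((y - mu) / sigma)`` per example.

    Uniform on (0,1) when the predictive Gaussians are probabilistically
    calibrated; the workhorse of isotonic regression recalibration.
    """
    gps.validate()
    return norm.cdf((gps.y_true - gps.mu) / gps.sigma)
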