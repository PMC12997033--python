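"""Regression reliability metrics, bin tables, and the error-vs-uncertainty
bivariate histogram.

Two complementary reliability frameworks are covered: *variance-based*
(does the predicted spread match the prediction error, per uncertainty bin —
ENCE and its RMV/RMSE bin table) and *coverage-based* (does the ground truth
fall inside central predictive intervals at the advertised frequency — PICP,
CCE and its coverage curve). CRPS and the Gaussian NLL are proper scoring
rules combining calibration with sharpness; MAE/MASE summarize point
accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core import (
    GaussianPredictionSet,
    IntervalPredictionSet,
    ValidationError,
)

__all__ = [
    "bin_table_reg",
    "ence",
    "crps_gaussian",
    "picp",
    "cce",
    "CoverageCurve",
    "nll_gaussian",
    "mae_mase",
    "bivariate_error_histogram",
    "DEFAULT_CCE_LEVELS",
]

#: 19 equally spaced central-coverage levels, 0.05 ... 0.95.
DEFAULT_CCE_LEVELS = tuple(np.round(np.arange(0.05, 0.951, 0.05), 2))


@dataclass
class CoverageCurve:
    """Nominal central-coverage levels and the observed coverage at each."""

    levels: np.ndarray
    empirical: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"level": self.levels, "empirical": self.empirical})


def bin_table_reg(
    gps: GaussianPredictionSet, n_bins: int = 10, scheme: str = "equal-mass"
) -> pd.DataFrame:
    """Uncertainty-binned RMV/RMSE table behind the regression reliability
    diagram.

    Examples are binned by predicted sigma (equal-mass by default — robust to
    heavy-tailed sigma distributions; equal-width available); each nonempty
    bin reports RMV = sqrt(mean predicted variance) and RMSE = sqrt(mean
    squared residual).
    """
    gps.validate()
    if len(gps) < n_bins:
        raise ValidationError("binning requires at least n_bins examples")
    sigma = gps.sigma
    if scheme == "equal-mass":
        order = np.argsort(sigma, kind="stable")
        ids = np.empty(len(sigma), dtype=int)
        for b, chunk in enumerate(np.array_split(order, n_bins)):
            ids[chunk] = b
    elif scheme == "equal-width":
        lo, hi = sigma.min(), sigma.max()
        width = (hi - lo) / n_bins or 1.0
        ids = np.clip(((sigma - lo) / width).astype(int), 0, n_bins - 1)
    else:
        raise ValidationError(f"unknown binning scheme {scheme!r}")
    sq_resid = (gps.y_true - gps.mu) ** 2
    rows = []
    for b in range(n_bins):
        mask = ids == b
        if not mask.any():
            continue
        rows.append(
            {
                "bin_id": b,
                "sigma_lo": float(sigma[mask].min()),
                "sigma_hi": float(sigma[mask].max()),
                "count": int(mask.sum()),
                "rmv": float(np.sqrt(gps.var[mask].mean())),
                "rmse": float(np.sqrt(sq_resid[mask].mean())),
            }
        )
    return pd.DataFrame(rows)


def ence(
    gps: GaussianPredictionSet,
    n_bins: int = 10,
    normalized: bool = True,
    weighted: bool = True,
) -> float:
    """Expected normalized calibration error.

    Default form: count-weighted average over sigma bins of
    ``|RMV - RMSE| / RMV``. Flags drop the RMV normalization or use a plain
    (unweighted) average over bins.
    """
    table = bin_table_reg(gps, n_bins=n_bins)
    rmv = table["rmv"].to_numpy()
    rmse = table["rmse"].to_numpy()
    if normalized and (rmv == 0).any():
        raise ValidationError("zero RMV bin; cannot normalize")
    per_bin = np.abs(rmv - rmse) / (rmv if normalized else 1.0)
    if weighted:
        w = table["count"].to_numpy() / table["count"].sum()
        return float(np.sum(w * per_bin))
    return float(per_bin.mean())


def crps_gaussian(gps: GaussianPredictionSet) -> float:
    """Mean continuous ranked probability score under the Gaussian closed
    form ``sigma * [z (2 Phi(z) - 1) + 2 phi(z) - 1/sqrt(pi)]`` with
    ``z = (y - mu)/sigma``. Reported in target units."""
    gps.validate()
    sigma = gps.sigma
    z = (gps.y_true - gps.mu) / sigma
    crps = sigma * (z * (2 * norm.cdf(z) - 1) + 2 * norm.pdf(z) - 1 / np.sqrt(np.pi))
    return float(crps.mean())


def picp(ips: IntervalPredictionSet) -> float:
    """Prediction interval coverage probability *ratio*: observed coverage
    divided by the nominal level. Optimal value is 1."""
    ips.validate()
    inside = (ips.y_true >= ips.lo) & (ips.y_true <= ips.hi)
    return float(inside.mean() / ips.nominal_level)


def cce(
    gps: GaussianPredictionSet, levels=DEFAULT_CCE_LEVELS
) -> tuple[float, CoverageCurve]:
    """Coverage calibration error over a grid of central-coverage levels.

    For each level ``c`` the central interval ``mu +/- z((1+c)/2) sigma`` is
    checked against the ground truth; CCE is the mean squared gap between
    nominal and observed coverage. Also returns the coverage curve for
    plotting.
    """
    gps.validate()
    levels = np.asarray(levels, dtype=float)
    if (np.diff(levels) <= 0).any() or not ((levels > 0) & (levels < 1)).all():
        raise ValidationError("levels must be ascending and inside (0,1)")
    z = norm.ppf((1 + levels) / 2)
    abs_std = np.abs(gps.y_true - gps.mu) / gps.sigma
    empirical = (abs_std[:, None] <= z[None, :]).mean(axis=0)
    value = float(np.mean((levels - empirical) ** 2))
    return value, CoverageCurve(levels=levels, empirical=empirical)


def nll_gaussian(gps: GaussianPredictionSet) -> float:
    """Mean Gaussian negative log-likelihood
    ``0.5 [ln(2 pi var) + (y - mu)^2 / var]``."""
    gps.validate()
    return float(
        np.mean(0.5 * (np.log(2 * np.pi * gps.var) + (gps.y_true - gps.mu) ** 2 / gps.var))
    )


def mae_mase(
    y_true, y_pred=None, baseline_constant: float = None
) -> tuple[float, float]:
    """Mean absolute error and its scaled form.

    MASE divides the MAE by the error of always predicting
    ``baseline_constant`` — conventionally the training-split median of the
    target — so values below 1 beat that naive baseline. Accepts either a
    :class:`~uqeval.core.GaussianPredictionSet` (means are the point
    predictions) as ``mae_mase(gps, baseline_constant=m)`` or explicit
    ``(y_true, y_pred)`` arrays.
    """
    if isinstance(y_true, GaussianPredictionSet):
        gps = y_true.validate()
        if y_pred is not None and baseline_constant is None:
            baseline_constant = y_pred
        y_true, y_pred = gps.y_true, gps.mu
    if baseline_constant is None:
        raise ValidationError("baseline_constant is required")
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    mae = float(np.mean(np.abs(y_true - y_pred)))
    baseline_mae = float(np.mean(np.abs(y_true - baseline_constant)))
    if baseline_mae == 0:
        raise ValidationError("baseline MAE is zero; MASE undefined")
    return mae, mae / baseline_mae


def bivariate_error_histogram(
    gps: GaussianPredictionSet, n_bins_x: int = 20, n_bins_y: int = 20
) -> dict:
    """2-D counts of (predicted sigma, absolute error) for the small-scale
    calibration plot.

    Returns the count grid, both edge arrays, and the identity line metadata
    (error equal to predicted sigma) that marks perfect per-example
    agreement.
    """
    gps.validate()
    sigma = gps.sigma
    abs_err = np.abs(gps.y_true - gps.mu)
    counts, x_edges, y_edges = np.histogram2d(
        sigma, abs_err, bins=(n_bins_x, n_bins_y)
    )
    return {
        "counts": counts,
        "sigma_edges": x_edges,
        "abs_error_edges": y_edges,
        "reference_line": "abs_error == sigma",
    }
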