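"""Classification reliability metrics and reliability-diagram bin tables.

Conventions (documented once, used everywhere):

* *confidence* is the probability of the predicted class,
  ``max(p1, 1 - p1)``, so it lives in [0.5, 1] for binary problems and
  matches the reliability-diagram axes (average confidence per bin vs.
  average accuracy);
* entropies are base-2 so they share the [0, 1] scale with error rates;
* binning discrepancies are *squared* differences by default, with absolute
  differences available for cross-literature comparison;
* default 10 bins, first/last edges inclusive, empty bins carry zero weight.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.stats import rankdata

from .aggregate import binary_entropy
from .core import BinaryPredictionSet, ValidationError

__all__ = [
    "bin_table_cls",
    "ece",
    "ace",
    "smece",
    "uce",
    "vce",
    "nll_cls",
    "auc",
    "balanced_accuracy",
]

_NLL_EPS = 1e-6


def _confidence(ps: BinaryPredictionSet) -> np.ndarray:
    p = np.asarray(ps.p1, dtype=float)
    return np.maximum(p, 1 - p)


def _correct(ps: BinaryPredictionSet) -> np.ndarray:
    pred = (np.asarray(ps.p1) >= 0.5).astype(float)
    return (pred == np.asarray(ps.y_true)).astype(float)


def _equal_width_ids(x: np.ndarray, lo: float, hi: float, n_bins: int) -> np.ndarray:
    width = (hi - lo) / n_bins
    ids = np.floor((x - lo) / width).astype(int)
    return np.clip(ids, 0, n_bins - 1)


def _equal_mass_ids(x: np.ndarray, n_bins: int) -> np.ndarray:
    order = np.argsort(x, kind="stable")
    ids = np.empty(len(x), dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        ids[chunk] = b
    return ids


def bin_table_cls(
    ps: BinaryPredictionSet,
    axis: str = "confidence",
    scheme: str = "equal-width",
    n_bins: int = 10,
) -> pd.DataFrame:
    """Per-bin reliability statistics behind the classification diagrams.

    ``axis`` is ``"confidence"`` (probability of the predicted class, range
    [0.5, 1]), ``"positive"`` (positive-class probability, range [0, 1]), or
    ``"entropy"`` (base-2, range [0, 1]); ``scheme`` is ``"equal-width"`` over the axis range or
    ``"equal-mass"`` (sort and split into near-equal counts). Returns one row
    per nonempty bin with the bin range, count, mean axis value, empirical
    accuracy, error rate, and the binary entropy of the bin accuracy.
    """
    ps.validate()
    if n_bins < 1:
        raise ValidationError("n_bins must be >= 1")
    if axis == "confidence":
        x, lo, hi = _confidence(ps), 0.5, 1.0
    elif axis == "positive":
        x, lo, hi = np.asarray(ps.p1, dtype=float), 0.0, 1.0
    elif axis == "entropy":
        x, lo, hi = binary_entropy(ps.p1, base=2), 0.0, 1.0
    else:
        raise ValidationError(f"unknown axis {axis!r}")
    # on the positive-probability axis the observed frequency is the positive
    # fraction, not the accuracy of the predicted class
    correct = np.asarray(ps.y_true, dtype=float) if axis == "positive" else _correct(ps)
    if scheme == "equal-width":
        ids = _equal_width_ids(x, lo, hi, n_bins)
    elif scheme == "equal-mass":
        ids = _equal_mass_ids(x, n_bins)
    else:
        raise ValidationError(f"unknown binning scheme {scheme!r}")

    rows = []
    for b in range(n_bins):
        mask = ids == b
        if not mask.any():
            continue
        acc = float(correct[mask].mean())
        rows.append(
            {
                "bin_id": b,
                "bin_lo": float(x[mask].min()),
                "bin_hi": float(x[mask].max()),
                "count": int(mask.sum()),
                "mean_axis": float(x[mask].mean()),
                "accuracy": acc,
                "error_rate": 1.0 - acc,
                "entropy_of_accuracy": float(binary_entropy(acc, base=2)),
            }
        )
    return pd.DataFrame(rows)


def _binned_discrepancy(table: pd.DataFrame, observed: str, mode: str) -> float:
    n = table["count"].sum()
    diff = table["mean_axis"].to_numpy() - table[observed].to_numpy()
    w = table["count"].to_numpy() / n
    if mode == "squared":
        return float(np.sum(w * diff**2))
    if mode == "absolute":
        return float(np.sum(w * np.abs(diff)))
    raise ValidationError(f"unknown discrepancy mode {mode!r}")


def ece(ps: BinaryPredictionSet, n_bins: int = 10, mode: str = "squared") -> float:
    """Expected calibration error over equal-width confidence bins.

    Count-weighted average of the (squared, by default) difference between
    mean confidence and empirical accuracy per bin.
    """
    table = bin_table_cls(ps, axis="confidence", scheme="equal-width", n_bins=n_bins)
    return _binned_discrepancy(table, "accuracy", mode)


def ace(ps: BinaryPredictionSet, n_bins: int = 10, mode: str = "squared") -> float:
    """Adaptive calibration error: as :func:`ece` but with equal-mass bins,
    accommodating sparse or skewed confidence distributions."""
    if len(ps) < n_bins:
        raise ValidationError("ACE requires at least n_bins examples")
    table = bin_table_cls(ps, axis="confidence", scheme="equal-mass", n_bins=n_bins)
    return _binned_discrepancy(table, "accuracy", mode)


def smece(ps: BinaryPredictionSet, n_grid: int = 1024, max_iter: int = 100) -> float:
    """Smooth expected calibration error (binning-free ECE variant).

    Calibration residuals ``correct_i - conf_i`` are kernel-smoothed along
    the confidence axis with a Gaussian kernel reflected at the [0, 1]
    boundaries; ``smECE(s)`` integrates the absolute smoothed residual mass.
    The reported value is the fixed point ``s* = smECE(s*)`` of the
    bandwidth, found by bisection on ``s in [1e-4, 1]`` — a self-consistent
    scale choice that needs no bin count.
    """
    ps.validate()
    if len(ps) < 2:
        raise ValidationError("smECE requires at least 2 examples")
    conf = _confidence(ps)
    resid = _correct(ps) - conf
    n = len(conf)
    idx = np.clip((conf * n_grid).astype(int), 0, n_grid - 1)
    hist = np.bincount(idx, weights=resid, minlength=n_grid)

    def smece_at(bw: float) -> float:
        smoothed = gaussian_filter1d(hist, sigma=bw * n_grid, mode="reflect")
        return float(np.abs(smoothed).sum() / n)

    lo, hi = 1e-4, 1.0
    if smece_at(lo) <= lo:
        return smece_at(lo)  # fixed point pinned at the floor bandwidth
    if smece_at(hi) >= hi:
        raise ValidationError(
            f"smECE fixed point not bracketed: smECE(1) = {smece_at(hi):.4f}"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if smece_at(mid) > mid:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-6:
            break
    else:
        raise ValidationError(
            f"smECE fixed-point bisection did not converge: bracket [{lo}, {hi}]"
        )
    return smece_at(0.5 * (lo + hi))


def uce(ps: BinaryPredictionSet, n_bins: int = 10, mode: str = "squared") -> float:
    """Uncertainty calibration error: predictions binned by predictive
    entropy, comparing mean entropy with the within-bin misclassification
    rate."""
    table = bin_table_cls(ps, axis="entropy", scheme="equal-width", n_bins=n_bins)
    return _binned_discrepancy(table, "error_rate", mode)


def vce(ps: BinaryPredictionSet, n_bins: int = 10, mode: str = "squared") -> float:
    """Variation calibration error: predictions binned by predictive entropy,
    comparing mean predicted entropy with the observed variation expressed as
    the binary entropy of the within-bin accuracy."""
    table = bin_table_cls(ps, axis="entropy", scheme="equal-width", n_bins=n_bins)
    return _binned_discrepancy(table, "entropy_of_accuracy", mode)


def nll_cls(ps: BinaryPredictionSet) -> float:
    """Mean negative log-likelihood (natural log) of the target classes,
    with probabilities clipped to ``[1e-6, 1 - 1e-6]``."""
    ps.validate()
    p = np.clip(ps.p1, _NLL_EPS, 1 - _NLL_EPS)
    y = ps.y_true
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log1p(-p)))


def auc(ps: BinaryPredictionSet) -> float:
    """Area under the ROC curve via the Mann-Whitney statistic: the fraction
    of (positive, negative) pairs ranked correctly, ties counted 1/2."""
    ps.validate()
    y = ps.y_true
    if len(np.unique(y)) < 2:
        raise ValidationError("AUC is undefined with a single class")
    ranks = rankdata(ps.p1)
    n1 = int(y.sum())
    n0 = len(y) - n1
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def balanced_accuracy(ps: BinaryPredictionSet, threshold: float = 0.5) -> float:
    """Mean of sensitivity and specificity at the decision threshold
    (predict positive when ``p1 >= threshold``)."""
    ps.validate()
    y = ps.y_true
    if len(np.unique(y)) < 2:
        raise ValidationError("balanced accuracy is undefined with a single class")
    pred = (np.asarray(ps.p1) >= threshold).astype(float)
    sens = float(pred[y == 1].mean())
    spec = float(1 - pred[y == 0].mean())
    return 0.5 * (sens + spec)
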