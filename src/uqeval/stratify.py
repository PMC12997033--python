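"""Adaptive (per-group) evaluation and paired bootstrap comparison.

Global calibration can hide compensating per-stratum defects: a set that is
overconfident on one ground-truth class and underconfident on the other can
score a near-zero global ECE while both per-class ECEs are large. Adaptive
evaluation recomputes each metric independently inside every group (e.g.
ground-truth class, patient stratum) and summarizes with an *unweighted*
macro average over groups.

Model comparison uses paired example-level bootstrap resampling of the
metric difference, with a percentile confidence interval and a two-sided
sign-based p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import metrics_cls, metrics_reg
from .convert import gaussian_to_interval
from .core import (
    BinaryPredictionSet,
    GaussianPredictionSet,
    GroupLabels,
    IntervalPredictionSet,
    QuantilePredictionSet,
    ValidationError,
)

__all__ = [
    "METRICS",
    "subset",
    "adaptive_evaluate",
    "StratifiedReport",
    "bootstrap_compare",
    "BootstrapComparison",
]


def subset(ps, mask: np.ndarray):
    """Row-subset of any prediction-set type (boolean or index array)."""
    if isinstance(ps, GaussianPredictionSet):
        return GaussianPredictionSet(ps.y_true[mask], ps.mu[mask], ps.var[mask])
    if isinstance(ps, BinaryPredictionSet):
        return BinaryPredictionSet(
            ps.y_true[mask],
            ps.p1[mask],
            None if ps.logit_mu is None else ps.logit_mu[mask],
            None if ps.logit_var is None else ps.logit_var[mask],
        )
    if isinstance(ps, QuantilePredictionSet):
        return QuantilePredictionSet(ps.y_true[mask], ps.levels, ps.q[mask])
    if isinstance(ps, IntervalPredictionSet):
        return IntervalPredictionSet(
            ps.y_true[mask], ps.lo[mask], ps.hi[mask], ps.nominal_level
        )
    raise ValidationError(f"cannot subset {type(ps).__name__}")


def _cce_scalar(gps):
    return metrics_reg.cce(gps)[0]


def _picp_at(n_sigma):
    def f(gps):
        return metrics_reg.picp(gaussian_to_interval(gps, n_sigma))

    return f


#: name -> (callable, prediction-set class, requires both classes in group)
METRICS: dict[str, tuple[Callable, type, bool]] = {
    "ece": (metrics_cls.ece, BinaryPredictionSet, False),
    "ece_abs": (lambda ps: metrics_cls.ece(ps, mode="absolute"), BinaryPredictionSet, False),
    "ace": (metrics_cls.ace, BinaryPredictionSet, False),
    "smece": (metrics_cls.smece, BinaryPredictionSet, False),
    "uce": (metrics_cls.uce, BinaryPredictionSet, False),
    "vce": (metrics_cls.vce, BinaryPredictionSet, False),
    "nll": (metrics_cls.nll_cls, BinaryPredictionSet, False),
    "auc": (metrics_cls.auc, BinaryPredictionSet, True),
    "balanced_accuracy": (metrics_cls.balanced_accuracy, BinaryPredictionSet, True),
    "ence": (metrics_reg.ence, GaussianPredictionSet, False),
    "crps": (metrics_reg.crps_gaussian, GaussianPredictionSet, False),
    "nll_gaussian": (metrics_reg.nll_gaussian, GaussianPredictionSet, False),
    "cce": (_cce_scalar, GaussianPredictionSet, False),
    "picp_1s": (_picp_at(1), GaussianPredictionSet, False),
    "picp_2s": (_picp_at(2), GaussianPredictionSet, False),
}


def _resolve_metric(metric) -> tuple[Callable, bool]:
    if callable(metric):
        return metric, False
    if metric not in METRICS:
        raise ValidationError(f"unknown metric {metric!r}")
    fn, _, needs_both = METRICS[metric]
    return fn, needs_both


@dataclass
class StratifiedReport:
    """Per-group metric table plus the unweighted macro average."""

    per_group: pd.DataFrame  # index: group label, columns: metrics
    macro: pd.Series  # unweighted mean over groups, per metric


def adaptive_evaluate(
    ps, groups: GroupLabels, metric_list: Sequence
) -> StratifiedReport:
    """Compute each metric independently within each group.

    Metrics that require both classes are skipped (NaN, with a warning) in
    single-class groups and excluded from their macro average. The macro
    average is the unweighted mean over groups.
    """
    ps.validate()
    groups.validate_for(ps)
    labels = np.asarray(groups.group)
    rows = {}
    for g in pd.unique(labels):
        sub = subset(ps, labels == g)
        row = {}
        for metric in metric_list:
            fn, needs_both = _resolve_metric(metric)
            name = metric if isinstance(metric, str) else getattr(metric, "__name__", "metric")
            if needs_both and len(np.unique(sub.y_true)) < 2:
                warnings.warn(
                    f"metric {name!r} skipped for single-class group {g!r}",
                    RuntimeWarning,
                    stacklevel=2,
                )
                row[name] = np.nan
                continue
            row[name] = fn(sub)
        rows[g] = row
    per_group = pd.DataFrame.from_dict(rows, orient="index")
    macro = per_group.mean(axis=0, skipna=True)
    return StratifiedReport(per_group=per_group, macro=macro)


@dataclass
class BootstrapComparison:
    """Paired bootstrap comparison of one metric between two prediction sets."""

    metric: str
    observed_diff: float  # metric(a) - metric(b) on the full sets
    mean_diff: float
    ci_low: float
    ci_high: float
    p_value: float
    n_boot: int


def bootstrap_compare(
    ps_a,
    ps_b,
    metric,
    n_boot: int = 2000,
    seed: int = 0,
    ci: float = 0.95,
) -> BootstrapComparison:
    """Paired example-level bootstrap of ``metric(a) - metric(b)``.

    Both sets must share the same ground truth. Each replicate resamples
    example indices with replacement (the same indices for both sets),
    recomputes the metric difference, and the percentile interval and
    two-sided p-value (``2 min(frac <= 0, frac >= 0)``, clipped to
    ``[1/n_boot, 1]``) summarize the replicate distribution.
    """
    ps_a.validate()
    ps_b.validate()
    if len(ps_a) != len(ps_b):
        raise ValidationError("prediction sets must have equal length")
    if not np.array_equal(ps_a.y_true, ps_b.y_true):
        raise ValidationError("prediction sets must share ground truth")
    fn, _ = _resolve_metric(metric)
    name = metric if isinstance(metric, str) else getattr(metric, "__name__", "metric")
    n = len(ps_a)
    rng = np.random.default_rng(seed)
    diffs = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        diffs[b] = fn(subset(ps_a, idx)) - fn(subset(ps_b, idx))
    alpha = 1 - ci
    lo, hi = np.quantile(diffs, [alpha / 2, 1 - alpha / 2])
    frac_le = float((diffs <= 0).mean())
    frac_ge = float((diffs >= 0).mean())
    p = float(np.clip(2 * min(frac_le, frac_ge), 1 / n_boot, 1.0))
    return BootstrapComparison(
        metric=name,
        observed_diff=float(fn(ps_a) - fn(ps_b)),
        mean_diff=float(diffs.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        p_value=p,
        n_boot=n_boot,
    )
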