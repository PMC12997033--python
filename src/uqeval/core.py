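"""Domain types for prediction sets, validation, and CSV serialization.

The toolkit evaluates *model outputs*, not signals: each prediction set pairs
per-example ground truth with one expression of a predictive distribution —
Gaussian parameters, quantiles at stated levels, central prediction intervals,
a binary class probability (optionally with a logit-scale mean/variance), or a
stack of K ensemble-member outputs prior to aggregation.

Conventions shared by every module:

* variance (never standard deviation) is the canonical regression spread
  field; ``sigma`` is always derived,
* optional logit fields are absent (``None``), never sentinel numbers,
* example indexing is 0-based, in error messages too.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "GaussianPredictionSet",
    "BinaryPredictionSet",
    "QuantilePredictionSet",
    "IntervalPredictionSet",
    "EnsembleStack",
    "GroupLabels",
    "ONE_SIGMA_LEVELS",
    "TWO_SIGMA_LEVELS",
    "validate_prediction_set",
    "read_prediction_set",
    "write_prediction_set",
    "read_ensemble_stack",
    "write_ensemble_stack",
]

#: Central-interval quantile levels at 1 and 2 Gaussian standard deviations,
#: as conventionally printed to 4 decimals.
ONE_SIGMA_LEVELS: tuple[float, float] = (0.1587, 0.8413)
TWO_SIGMA_LEVELS: tuple[float, float] = (0.0228, 0.9772)


class ValidationError(ValueError):
    """A prediction set violates one of its structural invariants."""


def _as_1d_float(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be 1-dimensional, got shape {arr.shape}")
    return arr


def _first_bad(mask: np.ndarray) -> int:
    return int(np.flatnonzero(mask)[0])


def _check_finite(arr: np.ndarray, name: str) -> None:
    bad = ~np.isfinite(arr)
    if bad.any():
        raise ValidationError(f"non-finite value in {name} at example {_first_bad(bad)}")


def _check_equal_length(n: int, arr: np.ndarray, name: str) -> None:
    if len(arr) != n:
        raise ValidationError(f"{name} has length {len(arr)}, expected {n}")


@dataclass
class GaussianPredictionSet:
    """Per-example Gaussian predictive distributions with ground truth.

    Parameters
    ----------
    y_true : array of real targets, task units (e.g. mmHg)
    mu : array of predicted means, same units
    var : array of predicted variances, units squared; strictly positive
    """

    y_true: np.ndarray
    mu: np.ndarray
    var: np.ndarray

    def __post_init__(self) -> None:
        self.y_true = _as_1d_float(self.y_true, "y_true")
        self.mu = _as_1d_float(self.mu, "mu")
        self.var = _as_1d_float(self.var, "var")

    def __len__(self) -> int:
        return len(self.y_true)

    @property
    def sigma(self) -> np.ndarray:
        return np.sqrt(self.var)

    def validate(self) -> "GaussianPredictionSet":
        if len(self.y_true) < 1:
            raise ValidationError("prediction set must contain at least one example")
        for name, arr in (("y_true", self.y_true), ("mu", self.mu), ("var", self.var)):
            _check_equal_length(len(self.y_true), arr, name)
            _check_finite(arr, name)
        nonpos = self.var <= 0
        if nonpos.any():
            raise ValidationError(
                f"variance must be positive; violated at example {_first_bad(nonpos)}"
            )
        return self


@dataclass
class BinaryPredictionSet:
    """Per-example positive-class probabilities with binary ground truth.

    ``logit_mu`` / ``logit_var`` carry an optional logit-scale Gaussian
    (mean, variance) as produced by variance-aware classifiers; they are
    present or absent together.
    """

    y_true: np.ndarray
    p1: np.ndarray
    logit_mu: Optional[np.ndarray] = None
    logit_var: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.y_true = _as_1d_float(self.y_true, "y_true")
        self.p1 = _as_1d_float(self.p1, "p1")
        if self.logit_mu is not None:
            self.logit_mu = _as_1d_float(self.logit_mu, "logit_mu")
        if self.logit_var is not None:
            self.logit_var = _as_1d_float(self.logit_var, "logit_var")

    def __len__(self) -> int:
        return len(self.y_true)

    @property
    def has_logits(self) -> bool:
        return self.logit_mu is not None

    def validate(self) -> "BinaryPredictionSet":
        if len(self.y_true) < 1:
            raise ValidationError("prediction set must contain at least one example")
        _check_equal_length(len(self.y_true), self.p1, "p1")
        _check_finite(self.y_true, "y_true")
        _check_finite(self.p1, "p1")
        bad_label = ~np.isin(self.y_true, (0.0, 1.0))
        if bad_label.any():
            raise ValidationError(
                f"label outside {{0,1}} at example {_first_bad(bad_label)}"
            )
        bad_p = (self.p1 < 0) | (self.p1 > 1)
        if bad_p.any():
            raise ValidationError(
                f"p1 outside [0,1] at example {_first_bad(bad_p)}"
            )
        if (self.logit_mu is None) != (self.logit_var is None):
            raise ValidationError("logit_mu and logit_var must be present together")
        if self.logit_mu is not None:
            _check_equal_length(len(self.y_true), self.logit_mu, "logit_mu")
            _check_equal_length(len(self.y_true), self.logit_var, "logit_var")
            _check_finite(self.logit_mu, "logit_mu")
            _check_finite(self.logit_var, "logit_var")
            neg = self.logit_var < 0
            if neg.any():
                raise ValidationError(
                    f"logit_var must be nonnegative; violated at example {_first_bad(neg)}"
                )
        return self


@dataclass
class QuantilePredictionSet:
    """Predicted quantiles at stated levels, one row per example.

    Default level pairs are the 1-sigma ``(0.1587, 0.8413)`` and 2-sigma
    ``(0.0228, 0.9772)`` central bands (:data:`ONE_SIGMA_LEVELS`,
    :data:`TWO_SIGMA_LEVELS`).
    """

    y_true: np.ndarray
    levels: tuple
    q: np.ndarray

    def __post_init__(self) -> None:
        self.y_true = _as_1d_float(self.y_true, "y_true")
        self.levels = tuple(float(l) for l in self.levels)
        self.q = np.asarray(self.q, dtype=float)
        if self.q.ndim == 1:
            self.q = self.q.reshape(-1, len(self.levels))

    def __len__(self) -> int:
        return len(self.y_true)

    def validate(self) -> "QuantilePredictionSet":
        if len(self.y_true) < 1:
            raise ValidationError("prediction set must contain at least one example")
        lv = np.asarray(self.levels)
        if not ((lv > 0).all() and (lv < 1).all()):
            raise ValidationError("levels must lie strictly inside (0,1)")
        if not (np.diff(lv) > 0).all():
            raise ValidationError("levels must be strictly increasing")
        if self.q.shape != (len(self.y_true), len(self.levels)):
            raise ValidationError(
                f"q has shape {self.q.shape}, expected {(len(self.y_true), len(self.levels))}"
            )
        _check_finite(self.y_true, "y_true")
        for j in range(self.q.shape[1]):
            _check_finite(self.q[:, j], f"q[:,{j}]")
        crossing = (np.diff(self.q, axis=1) < 0).any(axis=1)
        if crossing.any():
            raise ValidationError(f"quantile crossing at example {_first_bad(crossing)}")
        return self


@dataclass
class IntervalPredictionSet:
    """Central prediction intervals with a shared nominal coverage level."""

    y_true: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    nominal_level: float

    def __post_init__(self) -> None:
        self.y_true = _as_1d_float(self.y_true, "y_true")
        self.lo = _as_1d_float(self.lo, "lo")
        self.hi = _as_1d_float(self.hi, "hi")
        self.nominal_level = float(self.nominal_level)

    def __len__(self) -> int:
        return len(self.y_true)

    def validate(self) -> "IntervalPredictionSet":
        if len(self.y_true) < 1:
            raise ValidationError("prediction set must contain at least one example")
        for name, arr in (("y_true", self.y_true), ("lo", self.lo), ("hi", self.hi)):
            _check_equal_length(len(self.y_true), arr, name)
            _check_finite(arr, name)
        if not (0.0 < self.nominal_level < 1.0):
            raise ValidationError(
                f"nominal_level must lie in (0,1), got {self.nominal_level}"
            )
        inverted = self.lo > self.hi
        if inverted.any():
            raise ValidationError(
                f"interval with lo > hi at example {_first_bad(inverted)}"
            )
        return self


@dataclass
class EnsembleStack:
    """K member outputs sharing one ground truth, prior to aggregation.

    For regression ``member_mu``/``member_var`` are target-scale Gaussian
    parameters per member; for classification they are logit-scale means and
    variances. Both are ``(K, n)`` arrays.
    """

    task: str  # "regression" | "classification"
    y_true: np.ndarray
    member_mu: np.ndarray
    member_var: np.ndarray

    def __post_init__(self) -> None:
        self.y_true = _as_1d_float(self.y_true, "y_true")
        self.member_mu = np.atleast_2d(np.asarray(self.member_mu, dtype=float))
        self.member_var = np.atleast_2d(np.asarray(self.member_var, dtype=float))

    @property
    def n_members(self) -> int:
        return self.member_mu.shape[0]

    def __len__(self) -> int:
        return len(self.y_true)

    def validate(self) -> "EnsembleStack":
        if self.task not in ("regression", "classification"):
            raise ValidationError(f"unknown task {self.task!r}")
        if self.n_members < 1:
            raise ValidationError("ensemble stack must have at least one member")
        n = len(self.y_true)
        if n < 1:
            raise ValidationError("prediction set must contain at least one example")
        for name, arr in (("member_mu", self.member_mu), ("member_var", self.member_var)):
            if arr.shape != (self.n_members, n):
                raise ValidationError(
                    f"{name} has shape {arr.shape}, expected {(self.n_members, n)}"
                )
            _check_finite(arr.ravel(), name)
        if self.task == "regression":
            nonpos = (self.member_var <= 0).any(axis=0)
            if nonpos.any():
                raise ValidationError(
                    f"member variance must be positive; violated at example {_first_bad(nonpos)}"
                )
        else:
            neg = (self.member_var < 0).any(axis=0)
            if neg.any():
                raise ValidationError(
                    f"member logit_var must be nonnegative; violated at example {_first_bad(neg)}"
                )
        return self


@dataclass
class GroupLabels:
    """Categorical label per example, e.g. ground-truth class or patient stratum."""

    group: np.ndarray

    def __post_init__(self) -> None:
        self.group = np.asarray(self.group)

    def __len__(self) -> int:
        return len(self.group)

    def validate_for(self, ps) -> "GroupLabels":
        if len(self.group) != len(ps):
            raise ValidationError(
                f"group labels have length {len(self.group)}, expected {len(ps)}"
            )
        if len(np.unique(self.group)) < 1:
            raise ValidationError("at least one group is required")
        return self


def validate_prediction_set(ps):
    """Validate any prediction-set type and return it unchanged.

    Raises :class:`ValidationError` naming the first violated invariant and
    the offending (0-based) example index.
    """
    return ps.validate()


# ---------------------------------------------------------------------------
# CSV serialization
#
# Header-driven dialect: y_true,mu,var | y_true,p1[,logit_mu,logit_var] |
# y_true,q_<level to 4 decimals>,... | y_true,lo,hi with nominal_level in a
# sidecar JSON (<path>.json). Ensemble stacks use long format with member_id.
# ---------------------------------------------------------------------------


def _sidecar_path(path) -> Path:
    return Path(str(path) + ".json")


def write_prediction_set(ps, path) -> None:
    """Write a prediction set to CSV (interval sets also write a JSON sidecar)."""
    path = Path(path)
    if isinstance(ps, GaussianPredictionSet):
        df = pd.DataFrame({"y_true": ps.y_true, "mu": ps.mu, "var": ps.var})
    elif isinstance(ps, BinaryPredictionSet):
        cols = {"y_true": ps.y_true, "p1": ps.p1}
        if ps.has_logits:
            cols["logit_mu"] = ps.logit_mu
            cols["logit_var"] = ps.logit_var
        df = pd.DataFrame(cols)
    elif isinstance(ps, QuantilePredictionSet):
        cols = {"y_true": ps.y_true}
        for j, lvl in enumerate(ps.levels):
            cols[f"q_{lvl:.4f}"] = ps.q[:, j]
        df = pd.DataFrame(cols)
    elif isinstance(ps, IntervalPredictionSet):
        df = pd.DataFrame({"y_true": ps.y_true, "lo": ps.lo, "hi": ps.hi})
        _sidecar_path(path).write_text(
            json.dumps({"nominal_level": ps.nominal_level})
        )
    else:
        raise TypeError(f"cannot serialize {type(ps).__name__}")
    df.to_csv(path, index=False)


def read_prediction_set(path):
    """Read a prediction set from CSV, inferring its type from the header."""
    path = Path(path)
    df = pd.read_csv(path)
    cols = list(df.columns)
    if cols[:3] == ["y_true", "mu", "var"]:
        return GaussianPredictionSet(df["y_true"], df["mu"], df["var"]).validate()
    if cols[:2] == ["y_true", "p1"]:
        logit_mu = df["logit_mu"] if "logit_mu" in cols else None
        logit_var = df["logit_var"] if "logit_var" in cols else None
        return BinaryPredictionSet(df["y_true"], df["p1"], logit_mu, logit_var).validate()
    if cols[:3] == ["y_true", "lo", "hi"]:
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise ValidationError(f"interval CSV requires sidecar {sidecar}")
        meta = json.loads(sidecar.read_text())
        return IntervalPredictionSet(
            df["y_true"], df["lo"], df["hi"], meta["nominal_level"]
        ).validate()
    qcols = [c for c in cols if c.startswith("q_")]
    if cols[0] == "y_true" and qcols:
        levels = tuple(float(c[2:]) for c in qcols)
        return QuantilePredictionSet(
            df["y_true"], levels, df[qcols].to_numpy()
        ).validate()
    raise ValidationError(f"unrecognized prediction CSV header: {cols}")


def write_ensemble_stack(stack: EnsembleStack, path) -> None:
    """Write an ensemble stack as long-format CSV with a member_id column."""
    mu_col, var_col = (
        ("mu", "var") if stack.task == "regression" else ("logit_mu", "logit_var")
    )
    frames = []
    for k in range(stack.n_members):
        frames.append(
            pd.DataFrame(
                {
                    "member_id": k,
                    "y_true": stack.y_true,
                    mu_col: stack.member_mu[k],
                    var_col: stack.member_var[k],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_ensemble_stack(path) -> EnsembleStack:
    df = pd.read_csv(path)
    task = "regression" if "mu" in df.columns else "classification"
    mu_col, var_col = ("mu", "var") if task == "regression" else ("logit_mu", "logit_var")
    member_ids = sorted(df["member_id"].unique())
    mus, vars_, y = [], [], None
    for k in member_ids:
        sub = df[df["member_id"] == k]
        mus.append(sub[mu_col].to_numpy())
        vars_.append(sub[var_col].to_numpy())
        if y is None:
            y = sub["y_true"].to_numpy()
    return EnsembleStack(task, y, np.array(mus), np.array(vars_)).validate()
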