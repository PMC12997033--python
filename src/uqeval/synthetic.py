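"""Synthetic prediction sets with known, controllable calibration defects.

Every metric and recalibration method in this toolkit needs a test bed where
the ground truth about calibration is known exactly. The generators here
emulate the statistical shape of deep-model outputs on physiological tasks —
a blood-pressure-like regression target (means ~ Normal(115.48, 18.92^2)
mmHg) and an atrial-fibrillation-like imbalanced binary label (positive
fraction 0.38) — and inject *multiplicative* miscalibration:

* regression: the reported sigma is ``c`` times the true noise sigma, the
  exact defect variance scaling undoes;
* classification: the reported logit is ``T_true`` times the true logit, the
  exact defect temperature scaling undoes (fitting recovers ``T_true``;
  ``T_true > 1`` is overconfident).

``c = 1`` / ``T_true = 1`` produce perfectly calibrated sets. All generators
are pure functions of their config: the same config yields identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit

from .core import (
    BinaryPredictionSet,
    EnsembleStack,
    GaussianPredictionSet,
    ValidationError,
)

__all__ = [
    "RegressionSimConfig",
    "ClassificationSimConfig",
    "simulate_regression",
    "simulate_classification",
    "simulate_ensemble",
]


@dataclass
class RegressionSimConfig:
    """Configuration of the regression generator.

    n : number of examples.
    mu_center, mu_sd : distribution of predicted means; defaults give a
        systolic-blood-pressure-like target (115.48 +/- 18.92 mmHg).
    sigma_log_mean, sigma_log_sd : lognormal parameters of the true
        per-example noise sigma; defaults center the noise near 10 mmHg,
        the scale of per-example error of reasonable BP regressors.
    c : variance miscalibration factor — reported sigma = c * true sigma.
        c < 1 is overconfident, c > 1 underconfident, c = 1 calibrated.
    seed : RNG seed.
    """

    n: int
    mu_center: float = 115.48
    mu_sd: float = 18.92
    sigma_log_mean: float = float(np.log(10.0))
    sigma_log_sd: float = 0.25
    c: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("n must be >= 1")
        if self.c <= 0:
            raise ValidationError("miscalibration factor c must be positive")
        if not np.isfinite([self.sigma_log_mean, self.sigma_log_sd]).all():
            raise ValidationError("sigma parameters must be finite")


@dataclass
class ClassificationSimConfig:
    """Configuration of the classification generator.

    n : number of examples.
    pos_ratio : expected positive-class fraction (default 0.38,
        atrial-fibrillation-like imbalance).
    concentration : Beta concentration of the true per-example probability
        pi (mean pos_ratio); smaller values spread pi toward 0/1.
    T_true : logit temperature distortion — reported logit =
        T_true * logit(pi), so temperature scaling fitted on this data
        recovers T_true. T_true > 1 is overconfident, 1 is calibrated.
    logit_var_scale : mean of the exponentially distributed per-example
        logit variance attached to the set.
    seed : RNG seed.
    """

    n: int
    pos_ratio: float = 0.38
    concentration: float = 2.0
    T_true: float = 1.0
    logit_var_scale: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("n must be >= 1")
        if not (0 < self.pos_ratio < 1):
            raise ValidationError("pos_ratio must lie in (0,1)")
        if self.T_true <= 0:
            raise ValidationError("T_true must be positive")
        if self.logit_var_scale < 0:
            raise ValidationError("logit_var_scale must be nonnegative")


def simulate_regression(cfg: RegressionSimConfig) -> GaussianPredictionSet:
    """Draw a regression prediction set with known variance miscalibration.

    ``mu_i ~ Normal(mu_center, mu_sd^2)``; true noise
    ``sigma_i ~ Lognormal``; ``y_i ~ Normal(mu_i, sigma_i^2)``; the reported
    variance is ``(c * sigma_i)^2``.
    """
    rng = np.random.default_rng(cfg.seed)
    mu = rng.normal(cfg.mu_center, cfg.mu_sd, cfg.n)
    true_sigma = rng.lognormal(cfg.sigma_log_mean, cfg.sigma_log_sd, cfg.n)
    y = rng.normal(mu, true_sigma)
    reported_var = (cfg.c * true_sigma) ** 2
    return GaussianPredictionSet(y, mu, reported_var).validate()


def simulate_classification(cfg: ClassificationSimConfig) -> BinaryPredictionSet:
    """Draw a binary prediction set with known temperature miscalibration.

    True probabilities ``pi_i ~ Beta`` with mean ``pos_ratio``;
    ``y_i ~ Bernoulli(pi_i)``; reported
    ``p1 = logistic(T_true * logit(pi))``. The set carries
    ``logit_mu = logit(p1)`` and an exponential per-example logit variance.
    """
    rng = np.random.default_rng(cfg.seed)
    a = cfg.pos_ratio * cfg.concentration
    b = (1 - cfg.pos_ratio) * cfg.concentration
    pi = rng.beta(a, b, cfg.n)
    pi = np.clip(pi, 1e-6, 1 - 1e-6)
    y = (rng.random(cfg.n) < pi).astype(float)
    p1 = expit(cfg.T_true * logit(pi))
    logit_mu = logit(np.clip(p1, 1e-6, 1 - 1e-6))
    if cfg.logit_var_scale > 0:
        logit_var = rng.exponential(cfg.logit_var_scale, cfg.n)
    else:
        logit_var = np.zeros(cfg.n)
    return BinaryPredictionSet(y, p1, logit_mu, logit_var).validate()


def simulate_ensemble(
    cfg, K: int, jitter: float, seed: int | None = None
) -> EnsembleStack:
    """Draw an ensemble stack around a base prediction set.

    Member means are the base means jittered with independent
    ``Normal(0, jitter^2)`` noise; member variances equal the base reported
    variance, so law-of-total-variance aggregation recovers
    ``within-variance + jitter^2`` in expectation. Accepts either sim config;
    classification stacks live on the logit scale.
    """
    if K < 1:
        raise ValidationError("K must be >= 1")
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng((seed, 1))
    if isinstance(cfg, RegressionSimConfig):
        base = simulate_regression(cfg)
        center, within_var, y = base.mu, base.var, base.y_true
    elif isinstance(cfg, ClassificationSimConfig):
        base = simulate_classification(cfg)
        center, within_var, y = base.logit_mu, base.logit_var, base.y_true
    else:
        raise ValidationError(f"unsupported config type {type(cfg).__name__}")
    member_mu = center[None, :] + jitter * rng.standard_normal((K, len(y)))
    member_var = np.broadcast_to(within_var, (K, len(y))).copy()
    task = "regression" if isinstance(cfg, RegressionSimConfig) else "classification"
    return EnsembleStack(task, y, member_mu, member_var).validate()
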