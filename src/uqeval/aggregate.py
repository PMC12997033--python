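"""Aggregation of ensemble / Monte-Carlo member outputs into one predictive
distribution per example.

Regression members combine by the law of total variance: the aggregated
variance is the mean of member variances (aleatoric part) plus the population
variance of member means (epistemic part). Classification members combine by
Monte-Carlo sampling of noise-corrupted class probabilities: each member
contributes logistic-transformed draws from its logit-scale Gaussian, and the
aggregated probability is the grand mean over members and draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .core import (
    BinaryPredictionSet,
    EnsembleStack,
    GaussianPredictionSet,
    ValidationError,
)

__all__ = [
    "AggregationConfig",
    "aggregate_gaussian_members",
    "aggregate_binary_members",
    "predictive_entropy",
]


@dataclass
class AggregationConfig:
    """Configuration of classification aggregation.

    n_logit_samples : Monte-Carlo draws per member per example (default 100).
    seed : RNG seed; aggregation is bit-reproducible under a fixed seed.
    combine : where averaging happens — ``"probability"`` (post-sigmoid,
        default: mean of noise-corrupted class probabilities) or ``"logit"``
        (pre-sigmoid: logistic of the mean sampled logit).
    """

    n_logit_samples: int = 100
    seed: int = 0
    combine: str = "probability"

    def __post_init__(self) -> None:
        if self.n_logit_samples < 1:
            raise ValidationError("n_logit_samples must be >= 1")
        if self.combine not in ("probability", "logit"):
            raise ValidationError(f"unknown combine mode {self.combine!r}")


def aggregate_gaussian_members(stack: EnsembleStack) -> GaussianPredictionSet:
    """Combine regression members via the law of total variance.

    Per example: ``mu* = mean_k(mu_k)`` and
    ``var* = mean_k(var_k) + pop-var_k(mu_k)``. The population (divide-by-K)
    variance of member means is used: the members are the whole ensemble,
    not a sample from a larger one.
    """
    stack.validate()
    if stack.task != "regression":
        raise ValidationError("aggregate_gaussian_members requires a regression stack")
    mu_star = stack.member_mu.mean(axis=0)
    var_star = stack.member_var.mean(axis=0) + stack.member_mu.var(axis=0, ddof=0)
    return GaussianPredictionSet(stack.y_true, mu_star, var_star).validate()


def aggregate_binary_members(
    stack: EnsembleStack, cfg: AggregationConfig | None = None
) -> BinaryPredictionSet:
    """Aggregate classification members by Monte-Carlo logit sampling.

    For each member k and example i, draw ``cfg.n_logit_samples`` values
    ``z ~ Normal(logit_mu_k[i], logit_var_k[i])``, map through the logistic
    function, and average across all draws and members to obtain ``p1``. The
    result also carries the aggregated logit mean (mean of member logit means)
    and the law-of-total-variance logit variance.
    """
    stack.validate()
    if stack.task != "classification":
        raise ValidationError("aggregate_binary_members requires a classification stack")
    cfg = cfg or AggregationConfig()
    rng = np.random.default_rng(cfg.seed)
    K, n = stack.member_mu.shape
    # (K, S, n) draws; S*K values averaged per example
    z = rng.standard_normal((K, cfg.n_logit_samples, n))
    z = stack.member_mu[:, None, :] + np.sqrt(stack.member_var)[:, None, :] * z
    if cfg.combine == "probability":
        p1 = expit(z).mean(axis=(0, 1))
    else:
        p1 = expit(z.mean(axis=(0, 1)))
    logit_mu = stack.member_mu.mean(axis=0)
    logit_var = stack.member_var.mean(axis=0) + stack.member_mu.var(axis=0, ddof=0)
    return BinaryPredictionSet(stack.y_true, p1, logit_mu, logit_var).validate()


def predictive_entropy(ps: BinaryPredictionSet, base: float = 2) -> np.ndarray:
    """Entropy of each predicted Bernoulli distribution.

    ``H = -p log p - (1-p) log(1-p)`` in the requested base, with
    ``H(0) = H(1) = 0`` by continuity. Base 2 keeps binary entropies in
    [0, 1], unit-compatible with error rates.
    """
    p = np.asarray(ps.p1, dtype=float)
    return binary_entropy(p, base=base)


def binary_entropy(p, base: float = 2) -> np.ndarray:
    """Vectorized binary entropy with the 0·log 0 = 0 convention."""
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.where(p > 0, p * np.log(p), 0.0) - np.where(
            p < 1, (1 - p) * np.log1p(-p), 0.0
        )
    if base == 2:
        h = h / np.log(2)
    elif base not in (np.e, "e"):
        h = h / np.log(base)
    return h
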