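# Methods

This note records the models, conventions, and numerical choices behind
`uqeval`, and what the synthetic test bed does and does not establish about
real model outputs.

## Prediction-set model

Every operation works on one of five per-example output types: a Gaussian
predictive distribution (μ, σ²), a symmetric quantile pair at stated
levels, a central interval with one nominal coverage level, a Bernoulli
probability (optionally with a logit-scale mean/variance), or a stack of K
ensemble-member outputs. Variance — never standard deviation — is the
stored spread field, to keep units unambiguous (σ² in target-units²);
σ is always derived. Optional logit fields are absent, not sentinel-valued.
Validation reports the first violated invariant with its 0-based example
index; CSV round trips preserve values to better than 1e-12 because floats
are written with shortest-round-trip repr.

## Aggregation

Regression ensembles aggregate by the law of total variance. The variance
of member means uses the population (divide-by-K) convention: the K members
*are* the ensemble, not a sample from a larger population of models, so the
K−1 correction would be wrong in expectation for the quantity of interest.

Classification aggregation is Monte-Carlo: each member's logit-scale
Gaussian is sampled (`n_logit_samples` per member, default 100, seeded),
pushed through the logistic function and averaged — i.e. the aggregate is
the mean of noise-corrupted class probabilities, not the logistic of the
mean logit. With member logit variances of order 1, 100 samples put the
Monte-Carlo standard error on p below ~0.025/√K; raise `n_logit_samples`
when per-example (rather than population-level) probabilities matter. The
aggregated set also carries the law-of-total-variance logit variance so
downstream temperature scaling and Venn-ABERS can use a logit-scale score.

Entropies default to base 2 so binary predictive entropy lives in [0, 1]
and is unit-compatible with misclassification rates inside UCE/VCE.

## Conversion conventions

The point prediction of an interval or symmetric quantile pair is its
**midpoint**, not a median, so converted means compare like-for-like across
techniques whose native output is an interval. Spread is recovered with the
exact standard-normal quantile of the stated level: the upper 1σ level
0.8413 maps to z = 0.99982, not 1 — a ≤ 0.02 % difference, kept exact so
conversion pairs invert to 1e-12. Asymmetric quantile pairs are rejected
rather than symmetrized; only symmetric central bands have a defensible
Gaussian reconstruction.

## Recalibration

* **Temperature scaling** is fitted on aggregated (post-ensemble)
  probabilities, minimizing calibration NLL over T ∈ [0.05, 20] by bounded
  scalar search (tolerance 1e-6). Single-class calibration sets are
  rejected: NLL is then unbounded in T.
* **Variance scaling** uses the closed-form Gaussian-NLL minimizer
  s = mean((y−μ)²/σ²) — exact and deterministic. Zero-residual degeneracy
  clamps s to 1e-6 with a warning.
* **Isotonic regression (classification)** is a pool-adjacent-violators fit
  of label on probability (via scikit-learn), applied to test points as a
  **right-continuous step function** over the fitted knots. Piecewise
  constancy is preferred to linear interpolation because the PAV solution
  itself is piecewise constant; interpolation would invent intermediate
  calibrated values never supported by data. Outputs are clipped to
  [1e-6, 1−1e-6] before any log.
* **Isotonic regression (regression)** recalibrates through the PIT: the
  empirical CDF of calibration PIT values, fitted isotonically against
  nominal level, is inverted at the 1σ pair (0.1587, 0.8413); the test
  Gaussians are refit through the adjusted quantile pair. Fitting through a
  single symmetric pair keeps the output in the Gaussian family (the rest
  of the metric suite consumes (μ, σ²)); it corrects scale-type
  miscalibration exactly and skew-type miscalibration only at those two
  levels. At least 20 calibration examples are required; a constant PIT
  spread degenerates the map and warns.
* **Conformal prediction** uses the standard split-conformal order
  statistic: q̂ is the ⌈(n+1)(1−α)⌉-th smallest calibration score
  (standardized absolute residual |y−μ|/σ for Gaussian outputs; the CQR
  score max(q_lo−y, y−q_hi) for quantile pairs, which may be negative and
  then shrinks intervals). This rank is the smallest with a finite-sample
  marginal coverage guarantee ≥ 1−α under exchangeability; the upper edge
  of its expected coverage is 1−α+1/(n+1), which is what the guarantee
  test brackets. For 1σ/2σ reporting levels, α = 1−(2Φ(k)−1), k ∈ {1, 2}.
* **Venn-ABERS** refits two isotonic regressions per test example (label-0
  and label-1 augmented), giving the bracketing pair p0 ≤ p1 and the
  minimax-log-loss merge p = p1/(1−p0+p1). The direct O(n_test · n_calib
  log n_calib) refit is used instead of the incremental-update algorithm:
  it is transparent and fast at the calibration sizes this package targets
  (≤ ~10⁴). The underlying score is the probability by default, or the
  logit-scale mean when present.

## Metrics

Confidence is the probability of the *predicted* class, max(p, 1−p) ∈
[0.5, 1], matching reliability-diagram axes. Binned discrepancies
(ECE/ACE/UCE/VCE) use **squared** differences by default, with absolute
available for comparison with the larger ECE literature; note the squared
form is on a different scale (a constant 0.1 gap scores 0.01, not 0.1).
Equal-width bins partition the natural axis range (confidence [0.5, 1],
entropy [0, 1]); equal-mass bins sort and split into near-equal counts.
Default 10 bins, boundary edges inclusive, empty bins carry zero weight.

smECE replaces bins with a Gaussian kernel reflected at the [0, 1]
boundaries, computed on a 1024-cell histogram by reflected convolution. The
bandwidth is the fixed point s\* = smECE(s\*), found by bisection on
[1e-4, 1] (the map is monotone, so the fixed point is unique; the floor
value is returned when even the narrowest kernel shows less error than its
own width, i.e. for essentially calibrated data).

UCE compares mean bin entropy with the misclassification rate; VCE compares
it with the *binary entropy of the bin accuracy*, which expresses the
observed variation on the same entropy scale — this estimator of "observed
variation" is this package's documented choice. NLL is reported as a
per-example mean. AUC is the midrank Mann–Whitney statistic (ties count
1/2).

ENCE defaults to the normalized (|RMV−RMSE|/RMV), count-weighted form over
equal-mass sigma bins; both normalization and weighting are flags, because
unnormalized and unweighted variants appear in the literature. CRPS uses
the Gaussian closed form (cross-checked against direct quadrature of the
defining integral to 1e-6). PICP is reported as the ratio
observed/nominal coverage so its optimum is 1 at every level. CCE defaults
to 19 equally spaced levels 0.05…0.95 — dense enough to see scale
miscalibration anywhere in the central body, cheap to compute.

Stratified (adaptive) evaluation recomputes metrics within groups and
macro-averages **unweighted**, so minority strata count equally — the point
of adaptivity under class imbalance. Bootstrap comparison resamples
example indices (paired across the two prediction sets), with percentile
intervals; example-level resampling treats examples as exchangeable, so
within-patient correlation is ignored unless patient labels are passed as
the resampling unit by the caller.

## Synthetic test bed

The generators emulate the *statistical shape* of trained-model outputs on
two physiological tasks: regression means ~ Normal(115.48, 18.92²) (mmHg,
systolic-blood-pressure-like), true noise σ lognormal centered near
10 mmHg (the per-example error scale of competent BP regressors, σ_log_sd
0.25); classification true probabilities Beta-distributed with mean 0.38
(atrial-fibrillation-like imbalance, concentration 2 so probabilities
spread over most of [0, 1]).

Miscalibration is injected multiplicatively: reported σ = c · true σ, and
reported logit = T_true · true logit — so T_true > 1 means sharpened,
overconfident probabilities, and the fitted temperature-scaling parameter
equals T_true (dividing the reported logit by T_true restores the truth);
likewise variance scaling recovers s = 1/c². These are exactly the defect
families the scaling recalibrators can undo, enabling sharp
parameter-recovery tests; c = 1 / T_true = 1 yields perfectly calibrated
sets that pin every calibration metric near its optimum.

What passing on this test bed does **not** show: real model outputs have
input-dependent, non-multiplicative miscalibration, heteroscedastic defects
correlated with the target, distribution shift between calibration and
test splits (which breaks conformal exchangeability), and within-patient
correlation. The generators deliberately model none of these; results on
them validate the *machinery*, not any claim about a particular model.

## Problem sizes and determinism

Simulation-based checks use 2·10⁵ examples for coverage/variance
calibration limits, 2·10⁴–5·10⁴ for parameter recovery, and 500 replicates
of n = 1000 splits for the conformal guarantee — sizes at which
Monte-Carlo error is comfortably below each asserted tolerance. All
randomness flows through seeded `numpy.random.default_rng`; generators are
pure functions of their config, and the classification aggregator is
bit-reproducible under a fixed seed.

## Known limitations

Binary classification and scalar regression only; no multi-class
generalizations, no non-Gaussian parametric families, no Mondrian /
class-conditional conformal variants, no cross-conformal or jackknife+.
Venn-ABERS cost grows linearly in test-set size times an isotonic fit.
The regression isotonic recalibrator outputs Gaussians by design and so
cannot express non-Gaussian recalibrated shapes.
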