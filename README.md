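# uqeval

Evaluation and post-hoc recalibration of probabilistic predictions for
clinical machine-learning tasks.

Deep models used on physiological signals — blood-pressure regression from
PPG waveforms, atrial-fibrillation detection — increasingly report not just
a prediction but an uncertainty: a Gaussian mean and variance, a quantile
pair, a prediction interval, a class probability, or a stack of
ensemble-member outputs. Before such uncertainties can inform diagnosis they
must be *reliable*: the predicted spread has to match the observed error
frequency, globally, per uncertainty bin, and per patient stratum. `uqeval`
is a toolkit for exactly that audit. It is aimed at researchers comparing
uncertainty-quantification (UQ) techniques whose models are already trained:
the package consumes model *outputs* (tabular CSV or in-memory arrays),
never signals or weights.

## What it computes

**Aggregation** of K ensemble / Monte-Carlo-dropout members into one
predictive distribution per example. Regression members combine by the law
of total variance,

```
μ* = (1/K) Σₖ μₖ        σ*² = (1/K) Σₖ σₖ² + Varₖ(μₖ)
```

classification members by averaging logistic-transformed draws from each
member's logit-scale Gaussian.

**Conversions** between output types under a shared Gaussian assumption, so
every technique can be scored by every metric: symmetric quantile pairs at
the 1σ/2σ levels (0.1587/0.8413, 0.0228/0.9772) ↔ (μ, σ); Gaussians ↔
central intervals; probability integral transform (PIT) values.

**Post-hoc recalibration**, fitted on a held-out calibration split and
applied to test predictions: temperature scaling
`p(T) = σ(logit(p)/T)`, variance scaling `σ'² = s·σ²` with the closed-form
Gaussian-NLL minimizer `s = mean((y−μ)²/σ²)`, isotonic regression for
probabilities and for regression quantiles (through the PIT empirical CDF),
split conformal prediction (standardized-absolute score for Gaussian
outputs, CQR score for quantile pairs, both with the finite-sample
`⌈(n+1)(1−α)⌉` order statistic), and Venn-ABERS probability intervals.

**Metrics**, at three scales. Classification: ECE, adaptive-binned ACE,
kernel-smoothed smECE, entropy-binned UCE and VCE, NLL, AUC, balanced
accuracy, plus the per-bin tables behind reliability diagrams. Regression:
ENCE (per-bin |RMV−RMSE|/RMV), Gaussian closed-form CRPS, PICP ratio
(observed/nominal coverage; optimal value 1), CCE over a grid of coverage
levels with its coverage curve, Gaussian NLL, MAE/MASE, and the bivariate
error-vs-uncertainty histogram. **Stratified evaluation** recomputes any
metric per group (e.g. ground-truth class) with an unweighted macro
average, and a paired bootstrap compares two prediction sets on any metric.

**Synthetic generators** produce prediction sets with *known* calibration
defects — reported σ = c · true σ for regression, reported logit =
T_true · true logit for classification — so every metric and recalibration
method can be validated against ground truth.

## Worked example

Generate a deliberately overconfident regression model (reported sigmas are
half the true noise), recalibrate by variance scaling, and re-audit:

```python
import uqeval as uq

calib = uq.simulate_regression(uq.RegressionSimConfig(n=20_000, c=0.5, seed=0))
test  = uq.simulate_regression(uq.RegressionSimConfig(n=20_000, c=0.5, seed=1))

for label, ps in [("before", test)]:
    print(label, uq.ence(ps), uq.picp(uq.gaussian_to_interval(ps, 1)), uq.cce(ps)[0])

s, recal = uq.fit_variance_scale_reg(uq.CalibrationSplit(calib, test))
print("fitted scale", s)
print("after", uq.ence(recal), uq.picp(uq.gaussian_to_interval(recal, 1)), uq.cce(recal)[0])
```

Output (rounded):

```
before  ENCE 0.997   PICP(1σ) 0.569   CCE 0.0527
fitted scale 3.977
after   ENCE 0.011   PICP(1σ) 1.001   CCE 3.2e-06
```

Reading it: with σ reported at half its true value, RMSE is ~2× RMV in every
bin, so ENCE ≈ |1−2|/1 ≈ 1, and the 1σ intervals cover only ~0.39 of
observations instead of 0.68 (PICP ratio 0.57). Variance scaling recovers
the defect almost exactly (s ≈ 4 = 1/c², the variance correction for
c = 0.5); afterwards all three calibration metrics are at their optima
(ENCE ≈ 0, PICP ratio ≈ 1, CCE ≈ 0). The same workflow runs from the shell:

```sh
uqeval simulate --task regression --n 20000 --c 0.5 --seed 0 --out calib.csv
uqeval simulate --task regression --n 20000 --c 0.5 --seed 1 --out test.csv
uqeval recalibrate --method vs --calib calib.csv --test test.csv --out recal.csv
uqeval evaluate --pred recal.csv --out report.json
```

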