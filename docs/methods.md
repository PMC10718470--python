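# Methods

## Geometric estimators

Each lumbar level (L1–L5) is summarised by two linear measurements in
mm — the interpedicular distance (IPD) and the anteroposterior (AP)
canal diameter — and the estimators treat them as the axes of a simple
figure:

| shape     | formula            | factor on IPD·AP |
|-----------|--------------------|------------------|
| ellipse   | π·(IPD/2)·(AP/2)   | π/4 ≈ 0.7854     |
| triangle  | ½·IPD·AP           | 0.5              |
| rectangle | IPD·AP             | 1                |

All three are scalar multiples of the product P = IPD·AP. Two exact
consequences are load-bearing throughout the package and are enforced
by property tests:

1. **Correlation invariance.** Pearson r between any shape estimate and
   any reference series is identical across shapes (positive-affine
   invariance of r), so agreement tables carry one r per level.
2. **Collapse.** Any linear combination a·ellipse + b·triangle +
   c·rectangle equals (aπ/4 + b/2 + c)·P: a combined estimator built
   from these shapes has exactly one effective degree of freedom.

Units are fixed (mm, mm²); there is no conversion layer. All statistics
are computed in double precision; the 2-decimal (areas, percents),
3-decimal (r), and "<0.001" (p) rounding is applied only when rendering
the report, never to stored data.

## Agreement statistics

Per level × shape: mean difference MD = mean(estimate − manual) with
sample SD (n−1 denominator everywhere), a two-sided one-sample t-test
of the differences (t = MD/(SD/√n), df = n−1), aggregate percent error
100·MD/mean(manual), and Pearson r.

The aggregate (ratio-of-means) percent error is the default because it
is exactly consistent with the mean-difference table: percent error ≡
100·MD/mean(manual) for every (level, shape). A per-subject
mean-of-ratios mode is available (`mode="per_subject"`) and generally
differs; it weights small canals more heavily. Degenerate inputs —
fewer than two pairs, zero-variance differences, zero-variance series
for r — are rejected with explicit errors rather than returning NaN.

## Second-order estimator

By the collapse property, the only family reachable by combining the
three shapes is A ≈ k·P. The package fits k per level by least squares
through the origin,

    k̂ = Σ(A·P) / Σ(P²),

which minimises Σ(A − k·P)². For interpretability k̂ is re-expressed as
the convex combination w_e·(π/4) + w_t·(1/2) with w_e + w_t = 1, i.e.
w_e = (k̂ − ½)/(π/4 − ½); weights outside [0, 1] are reported with an
`extrapolating` flag rather than clipped. Per-level fitting is the
default because the effective manual/product ratio drifts caudally
(≈0.72 at L1 to ≈0.68 at L5, consistent with the canal becoming less
elliptical); a pooled fit is available by flag. Honest error estimates
come from shuffled k-fold cross-validation (default 5 folds, explicit
seed, pooled held-out RMSE); note that least squares through the origin
weights observations by P², so k̂ is close to but not identical to the
ratio of means mean(A)/mean(P).

## Synthetic cohort generator

The generator emulates the 555-patient CT reference cohort whose
per-level summary statistics (mean ± SD of the manual area and of the
rectangle estimate, which equals the product P, and the estimate-vs-
manual correlation) are the packaged calibration targets in
`src/canalarea/data/calibration.yaml`. Per level:

- manual area A ~ Normal(manual_mean, manual_sd²), truncated at 0 by
  resampling;
- product P = slope·A + intercept + Normal(0, noise_sd²), with
  slope = r·sd(P)/sd(A), intercept = mean(P) − slope·mean(A),
  noise_sd = sd(P)·√(1−r²), so mean(P), sd(P) and corr(A, P) hit their
  targets exactly in expectation;
- IPD ~ Normal(ipd_mean, (ipd_cv·ipd_mean)²) truncated at 0, and
  AP = P/IPD, so IPD·AP reproduces P to machine precision.

**Generative direction.** A is the latent truth and P is regressed on
it. The reverse direction (A = slope·P + independent noise) is
incompatible with the calibration targets: it would force
sd(A) ≥ r·slope-scaled sd(P) relationships that the printed SDs
contradict. A useful corollary: the implied SD of the paired
differences, e.g. sd(π/4·P − A) ≈ 23.9 mm² at L1, lands on the
published value without being targeted, which is independent evidence
the moment-matched bivariate model is the right generative family.

**Positivity.** Truncation at zero distorts moments negligibly here:
the zero bound sits more than 3.5 SDs below every calibrated mean
(coefficients of variation < 0.3). Two policies are exposed:
`resample` (default — redraw only the offending draw, preserving
accepted values) and `reject` (redraw the whole record jointly), with a
hard attempt budget of 10⁶.

**What is modelled and what is not.** The IPD marginal (default mean
24–28 mm cranio-caudally, CV 0.08) is an anatomically plausible
convenience: the reference tables print no IPD/AP marginals, and the
split affects only the IPD and AP columns, never the product, the
areas, or any agreement statistic. Cross-level correlation within a
patient is not modelled (levels are analysed independently), canal
shape is not modelled beyond the moments (no trefoil/stenotic
geometry), and the optional demographic columns (sex, age, height,
weight, BMI as independent truncated normals at the printed cohort
moments; age SD 5 y clipped to the 18–35 recruitment window) are
realism-only and never enter any statistic. Passing tests therefore
demonstrate correctness of the statistical pipeline under the
calibrated bivariate-normal model, not robustness to real-data features
such as skewed area distributions, inter-observer error structure, or
within-patient level correlation.

## Problem sizes and determinism

Every stochastic check runs with a fixed, explicit seed
(`numpy.random.default_rng`); cohorts are bit-reproducible given the
spec. The test suite exercises large-n recovery at 10⁵–1.5·10⁵ records
(sampling error well below the stated tolerances: e.g. SE(r) ≈ 6·10⁻⁴
at n = 10⁵ against a ±0.01 band) and study-scale behaviour at n = 555
over 200 seeds, comparing across-seed means to calibration targets
within two standard errors. The whole suite completes in a few seconds.

## Known limitations

- The second-order estimator is deliberately restricted to the
  one-parameter family k·IPD·AP; nonlinear families (superellipses,
  exponents on IPD or AP) could fit better but are outside the
  collapsed family the shape combination spans.
- Calibration reproduces first and second moments and the correlation;
  higher moments of the real cohort are unconstrained.
- The t-test assumes approximately normal differences; at the simulated
  scales this is exact by construction, but real cohorts may deviate.
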