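# Per-level generative calibration for the synthetic lumbar cohort.
#
# For each level: moments of the manually measured canal area (mm^2),
# moments of the product IPD * AP (mm^2, equal to the rectangle
# approximation), and the target Pearson correlation between any shape
# estimate and the manual area.  The generator derives the regression
# slope/intercept/noise from these so that the simulated cohort matches
# the moments and correlation in expectation.
#
# ipd_mean (mm) and ipd_cv control only how the product is split into
# IPD and AP; they never affect the product, the areas, or any
# agreement statistic.  The source cohort reports no IPD/AP marginals,
# so these are editable anatomically plausible defaults.
levels:
  L1:
    manual_mean: 281.78
    manual_sd: 48.89
    product_mean: 389.06
    product_sd: 71.93
    target_r: 0.907
    ipd_mean: 24.0
    ipd_cv: 0.08
  L2:
    manual_mean: 262.25
    manual_sd: 49.79
    product_mean: 363.32
    product_sd: 72.64
    target_r: 0.934
    ipd_mean: 24.5
    ipd_cv: 0.08
  L3:
    manual_mean: 253.28
    manual_sd: 49.93
    product_mean: 353.76
    product_sd: 74.04
    target_r: 0.909
    ipd_mean: 25.0
    ipd_cv: 0.08
  L4:
    manual_mean: 266.16
    manual_sd: 64.16
    product_mean: 384.82
    product_sd: 95.60
    target_r: 0.905
    ipd_mean: 26.0
    ipd_cv: 0.08
  L5:
    manual_mean: 318.50
    manual_sd: 90.23
    product_mean: 468.43
    product_sd: 128.07
    target_r: 0.931
    ipd_mean: 28.0
    ipd_cv: 0.08
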