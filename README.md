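# canalarea

Estimating the cross-sectional area of the lumbar spinal canal from two
linear measurements, and quantifying how well those estimates agree with
manually traced areas.

## The problem

The bony canal area at L1–L5 is the key morphometric quantity behind
lumbar spinal stenosis assessment, but tracing it on axial CT is slow.
Two linear measurements are fast and highly reproducible: the
interpedicular distance (IPD, the maximum distance between the medial
aspects of the pedicles, mm) and the anteroposterior (AP) diameter of
the canal (mm). Treating them as the axes of a simple figure gives
closed-form area estimates:

- ellipse: A = π · (IPD/2) · (AP/2)
- triangle: A = ½ · IPD · AP
- rectangle: A = IPD · AP

All three are scalar multiples of the product IPD·AP (factors π/4, ½, 1),
so they are perfectly collinear: they share one Pearson correlation with
any reference area, and any linear combination of them collapses to
k · IPD·AP for a single scalar k. That collapsed family is the
"second-order" estimator this package fits: k̂ by least squares through
the origin, k̂ = Σ(A·P)/Σ(P²) with P = IPD·AP, reported together with
the equivalent ellipse/triangle mixing weights and a cross-validated
RMSE.

Agreement with the manual measurement is summarised per level × shape
by the mean difference ± SD (estimate − manual), a two-sided paired
t-test, the signed aggregate percent error 100·MD/mean(manual), and
Pearson r.

Because the 555-patient reference cohort behind the published summary
tables is not deposited, the package includes a synthetic-cohort
generator moment-calibrated to those printed per-level means, SDs, and
correlations (bivariate-normal moment matching: the manual area is the
latent truth, the product IPD·AP is regression-generated from it). Every
statistic in the pipeline can therefore be exercised end-to-end with no
external data.

## Worked example

```sh
canalarea simulate --n 555 --seed 1 --out cohort.csv
canalarea report --in cohort.csv --second-order
```

prints (abridged):

```
Mean area by level (mm^2, mean±SD)
Level           Manual         Ellipse        Triangle       Rectangle
L1        280.16±45.66    301.83±53.31    192.15±33.94    384.31±67.88
L2        264.81±49.63    288.44±57.91    183.63±36.87    367.25±73.73
...

Agreement with manual measurement (difference = estimate - manual)
Level Shape          MD±SD (mm^2)         t        p       r
L1    ellipse         21.68±24.85     20.55   <0.001   0.885
L1    triangle       -88.00±22.21    -93.36   <0.001   0.885
L1    rectangle      104.15±34.72     70.66   <0.001   0.885
...

Percent error vs manual measurement
Level    Ellipse  Triangle Rectangle
L1         7.74%   -31.41%    37.18%
L2         8.92%   -30.66%    38.68%
...

Second-order scale factor (area ≈ k̂ · IPD · AP)
Level      k_hat  w_ellipse  w_triangle  train RMSE   CV RMSE  folds
L1        0.7250      0.788       0.212       23.02     23.07      5
L2        0.7177      0.763       0.237       17.68     17.71      5
L3        0.7110      0.739       0.261       21.87     21.94      5
L4        0.6843      0.646       0.354       27.87     27.89      5
L5        0.6813      0.635       0.365       34.02     34.05      5
```

Reading the output: at L1 the ellipse overestimates the manual area by
21.68 mm² on average (7.74% aggregate percent error), the triangle
underestimates and the rectangle grossly overestimates; all differences
are significant at n = 555; the single correlation per level (0.885 at
L1 in this draw) reflects the collinearity of the three estimators. The
fitted factor k̂ drifts from 0.725 at L1 to 0.681 at L5 — always
between the triangle (0.5) and ellipse (π/4 ≈ 0.785) factors,
equivalently a roughly 79/21 to 64/36 ellipse/triangle mixture — and
its training RMSE beats every fixed shape at the same level.

The same pipeline is available as a library: `generate_cohort`,
`evaluate_cohort`, `fit_cohort`, `build_report` in `canalarea`.

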