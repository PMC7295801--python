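# Methods

## The measurement model

Monochrome multiplex qPCR reads both amplicons (telomere repeat, T, and a
single-copy gene, S) in one well with one dye, yielding two quantification
cycles per well. Quantities are interpolated from per-plate, per-target
standard curves (ordinary least squares of Cq on log10 relative
concentration over a dilution series; at least three distinct dilutions
required). Amplification efficiency is reported as `10^(−1/slope) − 1`.

The T/S ratio is computed **per replicate and then averaged**; the
duplicate CV (sample sd / mean of per-replicate ratios, n−1 denominator)
is the QC statistic. The alternative "ratio of means" dialect is available
(`compute_ts_ratio(..., method="ratio_of_means")`) because raw-instrument
workflows differ on this point; with balanced duplicates and matched S
quantities the two coincide. The QC rule is strict: duplicate CV
*strictly greater* than the threshold (default 0.15) excludes a sample;
equality keeps it. Samples with no complete replicate are amplification
failures; samples with a single complete replicate have an undefined CV
and are likewise excluded. Intra-assay CV is the mean duplicate CV over
kept samples; inter-assay CV averages, over the reference and control
samples present on at least two plates, the cross-plate sd/mean of their
T/S values.

## Outcome normalization

Plates are batches: the pipeline always reports a one-way ANOVA of raw T/S
across plates, and the analysis outcome is the within-plate z-score
(sample sd). Plates with fewer than 3 QC-passed samples or zero spread
cannot support a z-score and are dropped with a logged reason.

Box-Cox is optional, for cohorts whose z-scores are visibly skewed. Two
dialects exist because z-scores contain negatives, which the raw power
transform cannot accept:

* `z_then_boxcox` (default): shift so the minimum maps to +0.01, transform
  with λ chosen by profile maximum likelihood on a fixed grid (−2…2, step
  1e−3 — deterministic by construction), then restandardize overall so the
  outcome remains in z-score units;
* `boxcox_then_z`: transform the strictly positive raw ratios first, then
  z-score per plate.

The shift, λ, and order are written to a JSON sidecar. The tiny-λ branch
uses `expm1(λ log x)/λ`, which stays accurate as λ → 0.

Skewed predictors (maternal BMI, maternal folate) enter models on the
natural-log scale; a non-positive value is a hard error naming row and
column.

## Seasonal regression

A conception date maps to θ = 2π(day_of_year − 1)/D with D the actual
length of that calendar year (365/366). A fixed-365.25 convention is
available (`convention="fixed_365_25"`); at these sample sizes the two are
indistinguishable, and the actual-year form keeps θ well defined for every
date.

The model is an ordinary Gaussian linear model with 2k Fourier columns
(sin jθ, cos jθ, j = 1…k) plus covariates; categorical covariates are
reference-coded with the alphabetically first level as reference. Each
model is fitted on its own complete cases, so reported N varies across
adjustment models — the missingness pattern real cohorts show. The
seasonal test is a likelihood-ratio test against the same-covariate model
without the Fourier columns, using Gaussian MLE log-likelihoods
(σ̂² = RSS/n, so ℓ = −(n/2)(log 2πσ̂² + 1)), referred to χ² with 2 df per
pair. An F-test variant would differ only at O(1/n); the LRT is the
package's default and its finite-sample size is verified by simulation
(see below). The number of pairs is chosen by sequential forward LRTs at
α = 0.05, never below k = 1; the trail of tests, including the k = 1 vs
baseline comparison, is recorded.

The seasonal effect size follows the max-minus-min convention: the fitted
mean (covariates held at sample means / reference levels) is evaluated on
a 366-point daily grid, and amplitude = max − min with peak/nadir the
argmax/argmin days. For k = 1 this agrees with the closed form
2√(a² + b²) up to the discretization bound 2√(a²+b²)(1 − cos(π/366)) ≈
3.7·10⁻⁵ relative, and the peak with atan2(a, b) within one day; both
identities are enforced in tests. Exact fits (RSS = 0) are flagged
degenerate — their log-likelihood is unbounded and their Wald band is
reported as zero width.

Uncertainty for amplitude and peak date comes from a case-resampling
bootstrap (percentile intervals; B ≥ 100, default 1000; rank-deficient
resamples are redrawn and counted). The peak-date interval is formed on
circular deviations recentred at the point estimate, so it behaves
correctly across the year boundary. Coverage of the amplitude interval at
the default study scale is ~94–95% by simulation.

Per-predictor effect models (`ltl_z ~ predictor + age + sex`) add one
Fourier pair when the predictor itself varies seasonally (maternal BMI,
birthweight, maternal folate), so a seasonal predictor is not credited
with the season effect. Wald t-tests use the unbiased covariance.

## Cell composition

Whole-blood telomere length depends on leukocyte mix, so models can adjust
for estimated cell-type fractions. Estimation is reference-based
constrained projection: minimise ‖profile − R·w‖² subject to w ≥ 0,
Σw = 1, solved by Lawson–Hanson active-set NNLS on a system augmented with
a heavily weighted (10³) sum-to-one row, then renormalized exactly onto
the simplex. Against an exhaustive simplex grid at resolution 0.001 the
solver attains an objective no worse than the best grid point and agrees
with it within twice the grid spacing. One fraction (granulocytes, the
largest) is dropped from regression designs to avoid the sum-to-one
collinearity. The module operates on synthetic six-type references
(B, CD4T, CD8T, Gran, Mono, NK); real 450k/EPIC array processing and the
published reference panels are out of scope.

## The synthetic-data generator

`generate_cohort` draws conception dates uniformly over a configurable
window (conception-rate seasonality is not modelled by default), applies a
seasonal effect s(θ) = (A/2)·cos(θ − θ_peak) with defaults **A = 0.6 z,
peak day 244, residual sd 1, n = 218** — the scale of a mid-childhood
cohort with a window-locked design — and adds covariate effects and
Gaussian noise. Collection dates are either `age_locked` (conception +
280-day gestation + 2 years, making collection date collinear with
conception date) or `window_locked` (uniform in a fixed Feb–May window).
Cohort presets: `emphasis_like()` (n = 218, window-locked, 55% male,
birthweight 3069 ± 417 g, two supplementation arms) and `enid_like()`
(n = 487, age-locked, 50% male, birthweight 3023 ± 402 g, maternal folate
measured, four maternal and two infant arms, ~29%/19% missingness in
maternal BMI/birthweight).

Covariates get mild seasonal components (birthweight ±50 g, BMI ±2%,
folate ±7.5% on the log scale) so that seasonal-confounder adjustment is
exercised; leukocyte fractions are Dirichlet draws around typical
childhood proportions.

`generate_plates` maps the latent z-scale outcome linearly to a raw T/S
(1.1 + 0.2·z, floored at 0.02), applies per-plate additive shifts
(sd 0.08) and multiplicative scales (log-sd 0.05) — an affine batch effect
that per-plate z-scoring removes exactly — and emits duplicate wells with
lognormal noise on both target quantities. The noise is calibrated so the
*expected reported* duplicate CV equals `duplicate_cv` (default 0.05),
which requires correcting for the c₄ = √(2/π) bias of a two-replicate
standard deviation. Each plate carries a 5-point dilution series per
target (noiseless by default, so curve recovery is exact), a reference
sample, and three control samples with true T/S 1.90/1.54/1.09 that drive
the inter-assay CV. An optional `qc_fail_fraction` inflates one replicate
of chosen samples so QC exclusion accounting can be tested exactly.

What the generator does **not** emulate: conception-rate seasonality,
infection history, breastfeeding, non-affine plate artefacts (position
effects, drift), instrument fluorescence processing, or real methylation
array structure. Passing tests therefore demonstrate correctness of the
*analysis* under the stated generative assumptions, not robustness to
every artefact of real plates.

## Verification scale and numerical choices

Simulation-based checks use: 1000 replicates for null calibration of the
2-df LRT at n = 218 (rejection rate must lie in the binomial band around
5%, and p-values pass a Kolmogorov–Smirnov uniformity check), 200
replicates for amplitude/peak recovery and bootstrap coverage (B = 400
per replicate), and single seeded runs for pipeline round trips. These
sizes give Monte-Carlo error comfortably below the tested tolerances
while keeping the default suite quick.

Other numerical choices: least squares via LAPACK QR (`lstsq`) with
rank-deficiency detection by pivoted QR, offending columns named in the
error; RSS at round-off scale (≤ 1e−24·‖y‖²) flagged as an exact fit;
Box-Cox λ grid step 1e−3; NNLS iteration cap 10⁴; all CVs with n−1
standard deviations; deterministic CSV/JSON formatting so identical
config + seed reproduces reports byte-for-byte.

## Known limitations

* Cross-sectional Gaussian linear models only — no mixed effects, GEE,
  splines, or multiple-testing correction across adjustment models.
* The amplitude point estimate inherits the positive bias of a max-minus-
  min statistic (≈ +0.02–0.05 z at the default scale); the bootstrap
  interval reflects, but does not bias-correct, this.
* Complete-case handling assumes missingness unrelated to outcome (MCAR
  is what the generator produces).
* The Box-Cox-on-z shift constant (minimum → +0.01) is a convention; both
  transform orders are provided because the right choice is data-dependent.
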