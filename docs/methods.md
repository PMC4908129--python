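# Methods

This note documents the statistical machinery, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate,
and the numerical conventions. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Data model and conventions

All inputs are 3D NIfTI-1 volumes on a single voxel grid; no resampling is
ever performed — a grid or affine mismatch is an error naming the
offending file. A mask voxel is in-mask iff its value > 0.5 (configurable),
which handles binary and probabilistic masks alike. In-mask voxels are
ordered by ascending linear index with the first axis varying fastest
(Fortran order, the on-disk NIfTI layout); parcellation and cluster
labeling both rely on this single ordering. Statistic maps are written as
32-bit float with out-of-mask voxels set to 0 (NaN selectable); 0 was
chosen for portability across viewers — the background value is a
convention, not a claim.

Masked data is held as an `n x τ` matrix. For chunked and parallel
fitting the voxel axis is split into `P` contiguous parcels (default
`P = 200`) of size `⌊τ/P⌋` or `⌈τ/P⌉`, with exactly `τ mod P` larger
parcels. Contiguous blocks maximize memory locality and make gather
trivial; any uniform partition satisfies the contract that matters, which
is partition invariance: every per-voxel computation depends only on that
voxel's data, so results are identical — bitwise — for any parcel count
and execution order. The shared-design linear fast path enforces this
trivially by computing the whole matrix in one vectorized pass.

## Model specification

Formulas are `response ~ t1 + t2 + a*b` with roles declared per symbol
(`scalar`, `factor`, `voxelwise`); `a*b` expands to both main effects plus
the product term, `a:b` adds only the product. Factors are treatment-coded
against the lexicographically first level (configurable); the original
literature this design follows reports single coefficients for binary
factors and is silent on coding, so results for factors may differ from
other toolboxes by the coding convention only. Interactions are
elementwise products of realized columns (dummy-block Kronecker products
when factors participate). Variable operations (negate, inverse, add c,
multiply c) apply in declaration order, before fitting; inverse requires
all-nonzero data and reports the count of offending values.

Sample filters are a deliberately small boolean grammar — comparisons on
columns, `& | !`, parentheses, string and numeric literals — instead of
evaluating arbitrary host-language expressions, so a table filter can
never execute code.

A binomial family with a voxel-wise response is rejected (a binary outcome
cannot be an image); other non-Gaussian families also require a scalar
response in the GLM engine, matching every reference use case.

## Linear engine

Per-voxel OLS via QR factorization (numerically safer than normal
equations); rank is declared deficient when the smallest |R_kk| falls
below `1e-10 · max(n,p) · max|R_kk|`. A rank-deficient voxel is NaN-ed and
flagged while the run continues; a rank-deficient *shared* design is a
hard error since every voxel would fail. Inference: `t = β̂/se`,
`df = n − rank(X)`, two-sided p from the T distribution. Perfect fits
(`se = 0`) report `t = ±inf`, `p = 0`, flagged. Subjects with NaN at a
voxel are dropped for that voxel only (per-voxel complete cases, df
adjusted); `strict=True` turns NaN into an error. The complete-cases
policy is this package's choice — the reference literature does not state
one.

## Generalized linear engine

In-house IRLS: weights `W = 1/(V(μ) g'(μ)²)`, working response
`z = η + (y−μ)g'(μ)`, weighted least squares by QR each iteration.
Convergence `|Δdeviance| < 1e-8`, max 100 iterations, family-standard mean
initialization. Default links: logit (binomial — the one link the
reference models state), log for Poisson, gamma and inverse-Gaussian
(strictly positive means with multiplicative effects — the common applied
choice); canonical links selectable. Scale fixed at 1 for
binomial/Poisson, Pearson-estimated for gamma/inverse-Gaussian. Inference
is Wald (`z = β̂/se` from the final weighted information), matching
per-parameter significance maps. Complete separation is detected by a
diverging linear predictor (|η| > 30) or a vanishing binomial deviance;
the voxel is flagged and NaN-ed rather than aborting — thousands of voxels
must not die on one degenerate fit.

Scaled odds ratios: `OR_j = exp(β̂_1j · sd_j)` with `sd_j` the sample SD
(ddof=1) of the predictor at voxel j, computed on the filtered analysis
sample after variable operations. This reads the "per one-SD increase"
caption convention literally; constant-predictor voxels get OR = 1 and a
flag. The interpretation is documented rather than claimed faithful.

## Mixed engine

One random intercept per group, `V = σ²_e (I + λ ZZ')`. REML profiled to
`λ = σ²_g/σ²_e`: for fixed λ, β̂ (GLS) and σ̂²_e are closed-form, and all
quantities accumulate group-by-group via the Woodbury identity, so no
n×n matrix is formed. The profiled criterion
`log|V₀| + (n−p) log σ̂²_e + log|X'V₀⁻¹X|` is minimized by bounded Brent
over `log λ ∈ [−10, 10]` (xatol 1e-8), with an explicit boundary
comparison: flat-near-zero profiles resolve to `σ²_g = 0`, where the fixed
effects coincide with OLS. Cohorts whose groups are all singletons leave λ
unidentifiable; they warn and fit OLS. Fixed-effect t maps use the
conservative `df = n − p − (n_groups − 1)`; the choice of df convention is
open in the literature this follows, and Satterthwaite-type corrections
are out of scope. Random slopes are not supported.

## Group tests and ROC

Two-sample t uses pooled variance by default (the classical default of the
underlying test), Welch by flag; the contrast is group1 − group2 in row
order. The paired t is exactly the one-sample t on per-subject
differences, rows aligned by subject id, `df = n_pairs − 1`. Zero-variance
voxels follow the `t = ±inf` convention with a flag.

ROC: prediction rule "positive when value ≥ threshold" (higher uptake =
more at risk; direction flippable). The empirical curve is computed over
distinct data values (ties collapse into one threshold), AUC by trapezoid
— algebraically the tie-corrected Mann-Whitney statistic — and the
operating point maximizes Youden's J = TPR − FPR, ties broken toward the
higher threshold. Which operating point the reference TPR maps used is not
stated anywhere; the Youden point is this package's documented choice.

## Cluster-extent correction

Defaults mirror the reference configuration: cluster-forming p < 0.001
(upper-tail T quantile at the model df), cluster-level p < 0.05,
6-connectivity.

Smoothness is estimated from standardized model residuals: each subject's
residual map is divided by the per-voxel SD, finite differences are taken
along each axis between in-mask neighbor pairs, and
`FWHM_a = sqrt(4 ln 2 / var(Δ_a u))` per axis;
`resels = τ / (FWHM_x FWHM_y FWHM_z)`. Under this estimator unsmoothed
noise reads FWHM ≈ sqrt(2 ln 2) ≈ 1.18 voxels — the correct continuum
limit does not exist for white noise, so sub-voxel readings simply mean
"unsmoothed". Users may instead supply the applied smoothing directly.

The cluster-size threshold uses the classical Gaussian-field
approximation: expected cluster count from the 3D Euler-characteristic
density `E[m] = R (4 ln 2)^{3/2} (2π)^{-2} (z²−1) e^{−z²/2}`, expected
suprathreshold volume `E[N] = τ Φ(−z)`, and size tail
`P(extent ≥ k) = exp(−β_c k^{2/3})` with `β_c = (Γ(5/2)/E[n])^{2/3}`;
the FWE of any cluster ≥ k is `1 − exp(−E[m] P(extent ≥ k))` and the
smallest qualifying integer k is returned in closed form. T maps are
converted to equivalent Gaussian z by upper-tail probability matching
before these formulae apply. The originating description names random
field theory without equations; this specific lineage is therefore a
design decision, validated by Monte-Carlo FWE measurement (500 smoothed
periodic null fields at FWHM 3 on a 40³ grid) rather than claimed
bit-faithful — the approximation runs conservative at these settings,
which the acceptance band accommodates. Thresholding is one-sided on the
signed statistic by default; two-sided mode thresholds |t| and doubles the
expected cluster count. BH-FDR is provided as the voxel-level alternative.

Labeling uses face adjacency (6-connectivity) on the scattered 3D map;
two-sided mode merges touching clusters of opposite sign (documented; run
one-sided twice to separate signs).

## Synthetic cohorts

The generator emulates the *statistical* structure of a multi-modal
PET/MRI cohort: per-subject volumes of Gaussian noise (SD 1.0) smoothed to
FWHM 2 voxels (σ = FWHM/√(8 ln 2)) on a 24³ grid with an inscribed
spherical mask, demographic-style covariates (AGE ~ N(72, 7), GENDER
Bernoulli(0.5), MMSE ~ N(27, 2.5) clipped, CDRSOB ~ N(2, 1.5) clipped at
0 — fixed study conditions chosen to resemble an aging-cohort table), and
region-localized effects. Effects are injected after smoothing, so the
in-region regressor is observed without attenuation and region edges are
sharp — unlike real activation. It does not emulate anatomy, PET physics,
or registration error; passing tests demonstrate estimator correctness
and calibration under the stated noise model, not robustness to real
acquisition artifacts. Null cohorts default to *unsmoothed* noise so
voxels are independent and Monte-Carlo standard errors over voxels are
exact. Identical arguments and seed give bit-identical cohorts and files;
table path columns are relative, so cohort directories are relocatable.
The multi-modal preset couples three modalities in one central sphere
(latent amyloid score → progression label and MMSE; FDG tracking VBM at
slope 0.6) to exercise every reference model shape end-to-end. A
95×117×99 grid — the reference analysis resolution — can be requested for
larger integration runs; tests use desk-scale grids (12³–40³) so the whole
suite stays under a minute.

## Problem sizes used in validation

Oracle equivalence runs at n = 50, τ = 5000; calibration at n = 100 on
~2000 independent voxels (the 3-MC-SE acceptance band is then ±0.0146
around 0.05; n = 100 keeps Wald-based logistic p-values near nominal);
recovery at n = 200 with a 552-voxel sphere; FWE measurement on 500 null
fields. These sizes make every check a few seconds at desk scale while
keeping Monte-Carlo bands meaningful.

## Known limitations

4D/time-series images, MINC/ANALYZE formats, and surface data are out of
scope (3D NIfTI-1 only). No generalized linear *mixed* models, random
slopes, crossed random effects, or Satterthwaite df. No robust/weighted
least squares or heteroscedasticity-consistent errors; single-df t maps
only (no F tests for multi-column terms). RFT here is cluster-extent only
(no peak-level inference, no permutation FWE, stationary smoothness
assumed). Parallelism is a process-local worker pool; distributed
execution is out of scope.
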