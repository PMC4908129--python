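# voxelwise

Mass-univariate statistics for multi-modal 3D brain images: fit one model
per voxel across a cohort of spatially normalized NIfTI-1 volumes, where
**any** variable — response, predictor, covariate, or interaction term —
may itself be an image.

Built for neuroimaging analysts working with multi-modal cohorts (PET
SUVR, VBM gray-matter density, FA/MD, perfusion, ...) who need voxel-wise
models richer than the classic "image response ~ scalar design": imaging
covariates, interactions between images, generalized-linear outcomes, and
longitudinal random-intercept models — with family-wise error control and
per-voxel ROC mapping in the same toolbox.

## The model

Image data for `n` subjects is masked and flattened to an `n x τ` matrix
(`τ` = in-mask voxels). At every voxel `j`, the declared formula is
realized by substituting column `j` of each voxel-wise variable and fit
independently:

- **Linear (OLS)** — e.g. `FDG[n×τ] ~ β0 + β1 VBM[n×τ] + β2 Age + β3 Gender`,
  with `t_k = β̂_k / se(β̂_k)`, `df = n − rank(X)`. A shared-design fast
  path factors `X` once when no covariate is voxel-wise.
- **Generalized linear (IRLS)** — binomial (logit), Poisson, gamma,
  inverse-Gaussian; Wald `z` maps; e.g.
  `ln(π/(1−π)) = β0 + β1 AmyloidPET[n×τ] + β2 Age + β3 Gender`, plus
  scaled odds-ratio maps `OR_j = exp(β̂_1j · SD_j)`.
- **Linear mixed** — one random intercept per group (subject), REML via a
  profiled one-dimensional search over `λ = σ²_g/σ²_e`.
- **Group tests** — voxel-wise pooled/Welch two-sample t and paired t.
- **ROC** — per-voxel AUC (trapezoid = tie-corrected rank statistic),
  TPR/FPR and threshold at the Youden point.
- **Correction** — cluster-forming threshold from the T distribution,
  residual-based smoothness (per-axis FWHM), random-field-theory
  cluster-size threshold, 6-connectivity labeling; BH-FDR as an
  alternative.

Arithmetic variable operations (negate, inverse, add/multiply by a
constant) can be attached to any scalar or image variable and are applied
before fitting. Masked voxels are split into 200 near-uniform parcels for
chunked/parallel fitting; results are independent of the parcel count.

## Worked example

`examples/01_voxelwise_regression.py` plants a β = 0.5 association between
a scalar score and the image inside a sphere, then fits
`IMG ~ SCORE + AGE` at every voxel:

```
voxels in mask: 4776, of which 552 in the sphere
mean beta inside sphere:  0.504   (true effect 0.5)
mean beta outside sphere: 0.001   (true effect 0)
mean |t| inside vs outside: 36.7 vs 0.8
```

The per-voxel slope estimates concentrate on the planted value inside the
sphere and on zero elsewhere; the |t| contrast shows the effect is
detected exactly where it exists. The other examples cover imaging
covariates and image×image interactions (02), logistic odds-ratio maps
(03), longitudinal mixed models (04), group tests and ROC (05), and
cluster correction (06).

The same analyses run from the shell via the `vxs` CLI:

```sh
vxs synth --n 60 --grid 24 24 24 --preset table1 --seed 9 --out cohort/
vxs lm  --table cohort/subjects.csv --mask cohort/mask.nii.gz \
        --roles roles.yaml --formula "FDG ~ VBM + AGE + GENDER" --out out/m2
vxs correct --stat out/m2_VBM_t.nii.gz --mask cohort/mask.nii.gz \
        --df 56 --fwhm 2 2 2 --out out/m2c
vxs view --map out/m2c_corrected.nii.gz --out out/m2c.png
```

Each model run writes one NIfTI map per statistic per term
(`<prefix>_<term>_<stat>.nii.gz`) plus a resolved-config YAML for
provenance.

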