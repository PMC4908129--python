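"""Synthetic cohorts with known ground truth.

Generates spatially smoothed noise volumes on a desk-scale grid (default
24^3 with an inscribed spherical "brain" mask), demographic-style scalar
covariates, and region-localized effects linking a covariate to the image
(or, for non-Gaussian families, the image to a generated response). Every
engine in the package is testable against these cohorts with no external
data: parameter-recovery cohorts embed a known beta inside a sphere, null
cohorts have no effect anywhere and drive calibration checks.

What it emulates: the statistical structure of a multi-modal PET/MRI
cohort — per-subject intensity maps with spatial autocorrelation, scalar
demographics, binary progression labels. What it does not: anatomy, PET
physics, registration error. Effects are injected *after* smoothing so the
in-region regressor is observed without attenuation; region edges are
therefore sharp, unlike real activation patterns.

Scalar covariate distributions (fixed study conditions): AGE ~ N(72, 7),
GENDER ~ Bernoulli(0.5) in {F, M}, MMSE ~ N(27, 2.5) clipped to [10, 30],
CDRSOB ~ N(2, 1.5) clipped at 0. Image noise SD 1.0, smoothing FWHM 2
voxels by default (0 for null cohorts, making voxels independent).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .volio import MaskGeometry, VoxelMatrix, mask_from_array, write_stat_map

__all__ = [
    "EffectSpec",
    "SynthCohort",
    "generate_cohort",
    "generate_null_cohort",
    "generate_table1_cohort",
    "smooth_volume",
    "sphere_indicator",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def smooth_volume(vol: np.ndarray, fwhm: float, mode: str = "nearest") -> np.ndarray:
    """Separable Gaussian smoothing with FWHM given in voxels."""
    if fwhm <= 0:
        return vol
    return gaussian_filter(vol, sigma=fwhm * FWHM_TO_SIGMA, mode=mode)


def sphere_indicator(grid: tuple[int, int, int], center, radius: float) -> np.ndarray:
    """Boolean sphere on the grid (voxel-center Euclidean distance)."""
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in grid), indexing="ij")
    c = np.asarray(center, dtype=float)
    d2 = (ii - c[0]) ** 2 + (jj - c[1]) ** 2 + (kk - c[2]) ** 2
    return d2 <= radius**2


@dataclass(frozen=True)
class EffectSpec:
    """A region-localized effect linking one variable to the image.

    ``region`` is ``("sphere", center, radius)`` or ``("box", lo, hi)``
    (inclusive corners). Semantics by family:

    * ``gaussian`` — the image gains ``beta * centered(variable)`` inside
      the region; fitting ``image ~ variable`` recovers ``beta`` there.
    * ``binomial`` — a latent N(0,1) subject score is added inside the
      region and the named binary column is drawn with
      ``P(1) = sigmoid(beta * score)``; voxel-wise logistic regression of
      the label on the image recovers ``beta`` there.
    * ``poisson`` — as binomial but the column is Poisson with log-rate
      ``intercept + beta * score``.
    """

    region: tuple
    variable: str
    beta: float
    family: str = "gaussian"
    intercept: float = 0.0

    def indicator(self, grid: tuple[int, int, int]) -> np.ndarray:
        kind = self.region[0]
        if kind == "sphere":
            _, center, radius = self.region
            ind = sphere_indicator(grid, center, radius)
        elif kind == "box":
            _, lo, hi = self.region
            if any(l < 0 for l in lo) or any(h >= s for h, s in zip(hi, grid)):
                raise ValueError(f"box region {self.region} outside grid {grid}")
            ind = np.zeros(grid, dtype=bool)
            ind[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] = True
        else:
            raise ValueError(f"unknown region kind {kind!r}")
        if not ind.any():
            raise ValueError(f"region {self.region} contains no voxels on grid {grid}")
        if kind == "sphere":
            _, center, radius = self.region
            if any(c - radius < 0 or c + radius >= s for c, s in zip(center, grid)):
                raise ValueError(f"sphere region {self.region} outside grid {grid}")
        return ind


@dataclass
class SynthCohort:
    """In-memory synthetic cohort plus (optionally) the files written for it."""

    table: pd.DataFrame
    geometry: MaskGeometry
    images: dict[str, VoxelMatrix]
    truth: dict[str, np.ndarray] = field(default_factory=dict)  # per-voxel true beta
    out_dir: str | None = None


def _default_mask(grid: tuple[int, int, int], kind: str) -> np.ndarray:
    if kind == "full":
        return np.ones(grid, dtype=float)
    if kind == "sphere":
        center = [(s - 1) / 2.0 for s in grid]
        radius = min(grid) / 2.0 - 1.5
        return sphere_indicator(grid, center, radius).astype(float)
    raise ValueError(f"mask must be 'sphere' or 'full', got {kind!r}")


def _demographics(n: int, rng: np.random.Generator) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "SUBJECT_ID": [f"sub-{i:04d}" for i in range(n)],
            "AGE": np.round(rng.normal(72.0, 7.0, n), 1),
            "GENDER": np.where(rng.random(n) < 0.5, "F", "M"),
            "MMSE": np.round(np.clip(rng.normal(27.0, 2.5, n), 10, 30), 0),
            "CDRSOB": np.round(np.clip(rng.normal(2.0, 1.5, n), 0, None), 1),
        }
    )


def generate_cohort(
    n: int,
    grid: tuple[int, int, int] = (24, 24, 24),
    effects: tuple[EffectSpec, ...] = (),
    seed: int = 0,
    noise_sd: float = 1.0,
    smoothing_fwhm: float = 2.0,
    baseline: float = 1.0,
    modality: str = "IMG",
    mask: str = "sphere",
    out_dir: str | os.PathLike | None = None,
) -> SynthCohort:
    """One-modality synthetic cohort with optional region-localized effects.

    Identical arguments (including ``seed``) give bit-identical cohorts.
    When ``out_dir`` is given, per-subject volumes, the mask, the subject
    table (with a ``<modality>_PATH`` column) and per-effect ground-truth
    beta maps are written there.
    """
    if n < 4:
        raise ValueError("need at least 4 subjects")
    if any(s < 8 for s in grid):
        raise ValueError("each grid axis must be >= 8")
    rng = np.random.default_rng(seed)
    table = _demographics(n, rng)
    geometry = mask_from_array(_default_mask(grid, mask))

    vols = np.empty((n,) + tuple(grid))
    for i in range(n):
        noise = rng.standard_normal(grid)
        vols[i] = baseline + noise_sd * smooth_volume(noise, smoothing_fwhm)

    truth: dict[str, np.ndarray] = {}
    for eff in effects:
        ind = eff.indicator(grid)
        if eff.family == "gaussian":
            if eff.variable in table.columns:
                x = table[eff.variable].to_numpy(dtype=float)
            else:
                x = rng.standard_normal(n)
                table[eff.variable] = x
            xc = x - x.mean()
            vols[:, ind] += eff.beta * xc[:, None]
        elif eff.family in ("binomial", "poisson"):
            score = rng.standard_normal(n)
            vols[:, ind] += score[:, None]
            eta = eff.intercept + eff.beta * score
            if eff.family == "binomial":
                table[eff.variable] = rng.binomial(1, 1.0 / (1.0 + np.exp(-eta)))
            else:
                table[eff.variable] = rng.poisson(np.exp(eta))
        else:
            raise ValueError(f"unknown effect family {eff.family!r}")
        tmap = np.where(ind.ravel(order="F")[geometry.voxel_index], eff.beta, 0.0)
        key = f"{eff.variable}"
        truth[key] = truth.get(key, 0.0) + tmap

    # stack in mask voxel order (Fortran linear indices)
    data = np.empty((n, geometry.tau))
    for i in range(n):
        data[i] = vols[i].ravel(order="F")[geometry.voxel_index]
    images = {modality: VoxelMatrix(data=data, geometry=geometry,
                                    subject_ids=table["SUBJECT_ID"].tolist())}

    cohort = SynthCohort(table=table, geometry=geometry, images=images, truth=truth)
    if out_dir is not None:
        _write_cohort(cohort, vols, modality, out_dir)
    return cohort


def _write_cohort(cohort: SynthCohort, vols: np.ndarray, modality: str, out_dir) -> None:
    import nibabel as nib

    os.makedirs(out_dir, exist_ok=True)
    geom = cohort.geometry
    mask_img = nib.Nifti1Image(geom.mask_array.astype(np.float32), geom.affine)
    nib.save(mask_img, os.path.join(out_dir, "mask.nii.gz"))
    # path columns hold names relative to the table, so the directory is relocatable
    paths = []
    for i, sid in enumerate(cohort.table["SUBJECT_ID"]):
        fname = f"{sid}_{modality}.nii.gz"
        nib.save(
            nib.Nifti1Image(vols[i].astype(np.float32), geom.affine),
            os.path.join(out_dir, fname),
        )
        paths.append(fname)
    cohort.table[f"{modality}_PATH"] = paths
    for var, tmap in cohort.truth.items():
        write_stat_map(tmap, geom, os.path.join(out_dir, f"truth_{var}_beta.nii.gz"))
    cohort.table.to_csv(os.path.join(out_dir, "subjects.csv"), index=False)
    cohort.out_dir = str(out_dir)


def generate_null_cohort(
    n: int,
    grid: tuple[int, int, int] = (24, 24, 24),
    seed: int = 0,
    smoothing_fwhm: float = 0.0,
    mask: str = "sphere",
    out_dir: str | os.PathLike | None = None,
) -> SynthCohort:
    """Cohort with zero effects everywhere, for calibration checks.

    Unsmoothed by default so voxels are independent and Monte-Carlo
    standard errors over voxels are exact. A binary ``PROGRESSION`` column
    (independent of everything) is included for null logistic/ROC checks.
    """
    cohort = generate_cohort(
        n,
        grid=grid,
        effects=(),
        seed=seed,
        smoothing_fwhm=smoothing_fwhm,
        mask=mask,
        out_dir=out_dir,
    )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    cohort.table["PROGRESSION"] = rng.binomial(1, 0.5, n)
    if out_dir is not None:
        cohort.table.to_csv(os.path.join(out_dir, "subjects.csv"), index=False)
    return cohort


def generate_table1_cohort(
    n: int = 60,
    grid: tuple[int, int, int] = (24, 24, 24),
    seed: int = 0,
    out_dir: str | os.PathLike | None = None,
) -> SynthCohort:
    """Multi-modal cohort shaped like the reference analyses.

    Three modalities on one grid — AMY (amyloid-PET-like), FDG
    (metabolism-like) and VBM (gray-matter-density-like) — plus MMSE,
    CDRSOB, AGE, GENDER and a binary PROGRESSION label. Couplings, all in
    one central sphere: AMY carries a latent subject score that drives
    PROGRESSION (logistic, beta=1) and lowers MMSE; FDG tracks VBM
    voxel-for-voxel (slope 0.6); CDRSOB rises with the AMY score.
    """
    rng = np.random.default_rng(seed)
    center = [(s - 1) / 2.0 for s in grid]
    radius = min(grid) / 4.0
    sphere = ("sphere", center, radius)

    amy = generate_cohort(
        n, grid, effects=(EffectSpec(sphere, "PROGRESSION", 1.0, family="binomial"),),
        seed=seed, modality="AMY", out_dir=None,
    )
    table = amy.table
    geometry = amy.geometry
    ind = EffectSpec(sphere, "x", 1.0).indicator(grid)
    ind_vec = ind.ravel(order="F")[geometry.voxel_index]

    vbm_noise = np.array(
        [smooth_volume(rng.standard_normal(grid), 2.0) for _ in range(n)]
    )
    vbm_data = 1.0 + np.stack(
        [v.ravel(order="F")[geometry.voxel_index] for v in vbm_noise]
    )
    fdg_noise = np.array(
        [smooth_volume(rng.standard_normal(grid), 2.0) for _ in range(n)]
    )
    fdg_data = 1.0 + 0.6 * np.stack(
        [v.ravel(order="F")[geometry.voxel_index] for v in fdg_noise]
    )
    fdg_data[:, ind_vec] = (
        0.6 * vbm_data[:, ind_vec]
        + 0.4
        + 0.5 * np.stack([v.ravel(order="F")[geometry.voxel_index] for v in fdg_noise])[:, ind_vec]
    )
    ids = table["SUBJECT_ID"].tolist()
    images = {
        "AMY": amy.images["AMY"],
        "VBM": VoxelMatrix(vbm_data, geometry, ids),
        "FDG": VoxelMatrix(fdg_data, geometry, ids),
    }
    score = amy.images["AMY"].data[:, ind_vec].mean(axis=1) - 1.0
    table["MMSE"] = np.round(np.clip(27.0 - 1.5 * score + rng.normal(0, 1.0, n), 10, 30), 0)
    table["CDRSOB"] = np.round(np.clip(2.0 + 1.2 * score + rng.normal(0, 1.0, n), 0, None), 1)

    truth = dict(amy.truth)
    truth["VBM->FDG"] = np.where(ind_vec, 0.6, 0.0)
    cohort = SynthCohort(table=table, geometry=geometry, images=images, truth=truth)
    if out_dir is not None:
        import nibabel as nib

        os.makedirs(out_dir, exist_ok=True)
        nib.save(
            nib.Nifti1Image(geometry.mask_array.astype(np.float32), geometry.affine),
            os.path.join(out_dir, "mask.nii.gz"),
        )
        all_paths: dict[str, list[str]] = {}
        from .volio import scatter_to_volume

        for mod, vm in images.items():
            paths = []
            for i, sid in enumerate(ids):
                vol = scatter_to_volume(vm.data[i], geometry).astype(np.float32)
                fname = f"{sid}_{mod}.nii.gz"
                nib.save(nib.Nifti1Image(vol, geometry.affine),
                         os.path.join(out_dir, fname))
                paths.append(fname)
            all_paths[f"{mod}_PATH"] = paths
        for col, paths in all_paths.items():
            table[col] = paths
        for var, tmap in truth.items():
            safe = var.replace(">", "").replace("-", "_")
            write_stat_map(tmap, geometry, os.path.join(out_dir, f"truth_{safe}_beta.nii.gz"))
        table.to_csv(os.path.join(out_dir, "subjects.csv"), index=False)
        cohort.out_dir = str(out_dir)
    return cohort
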