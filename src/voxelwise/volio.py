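"""NIfTI-1 volume I/O and the image-space <-> matrix-space conversion.

Mass-univariate analysis works on a 2D view of the cohort: an ``n_subjects x
tau`` matrix whose columns are the in-mask voxels of each subject's volume.
This module owns that conversion (stacking a cohort of 3D volumes into a
:class:`VoxelMatrix` and scattering per-voxel statistics back into 3D maps)
plus the mask bookkeeping (:class:`MaskGeometry`).

Voxel ordering is ascending linear index with the *first* axis varying
fastest (Fortran order), matching the on-disk NIfTI layout; every module that
consumes ``voxel_index`` (parcellation, cluster labeling) relies on this one
convention.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "MaskGeometry",
    "VoxelMatrix",
    "read_volume",
    "load_mask",
    "mask_from_array",
    "stack_cohort",
    "scatter_to_volume",
    "write_stat_map",
]


@dataclass(frozen=True)
class MaskGeometry:
    """Geometry of the analysis mask.

    Parameters
    ----------
    shape
        Voxel grid ``(nx, ny, nz)``.
    affine
        4x4 voxel-to-world transform, copied to every output map.
    voxel_index
        Strictly increasing linear indices (Fortran order, first axis
        fastest) of the in-mask voxels.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray
    voxel_index: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.voxel_index, dtype=np.intp)
        object.__setattr__(self, "voxel_index", idx)
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=float))
        if len(self.shape) != 3 or any(s <= 0 for s in self.shape):
            raise ValueError(f"mask shape must be 3 positive integers, got {self.shape}")
        if idx.size == 0:
            raise ValueError("empty mask: no voxel exceeds the threshold")
        if np.any(np.diff(idx) <= 0):
            raise ValueError("voxel_index must be strictly increasing")
        if idx[-1] >= int(np.prod(self.shape)):
            raise ValueError("voxel_index out of bounds for mask shape")

    @property
    def tau(self) -> int:
        """Number of in-mask voxels."""
        return int(self.voxel_index.size)

    @property
    def mask_array(self) -> np.ndarray:
        """Boolean 3D mask array."""
        flat = np.zeros(int(np.prod(self.shape)), dtype=bool)
        flat[self.voxel_index] = True
        return flat.reshape(self.shape, order="F")

    def coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(i, j, k) integer coordinates of in-mask voxels, in voxel order."""
        return np.unravel_index(self.voxel_index, self.shape, order="F")


@dataclass
class VoxelMatrix:
    """Masked cohort data: one row per subject, one column per in-mask voxel."""

    data: np.ndarray
    geometry: MaskGeometry
    subject_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("VoxelMatrix data must be 2D (subjects x voxels)")
        if self.data.shape[1] != self.geometry.tau:
            raise ValueError(
                f"data has {self.data.shape[1]} columns but mask has "
                f"{self.geometry.tau} voxels"
            )
        if not self.subject_ids:
            self.subject_ids = list(range(self.data.shape[0]))
        if len(self.subject_ids) != self.data.shape[0]:
            raise ValueError("subject_ids length does not match row count")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def tau(self) -> int:
        return self.data.shape[1]


def read_volume(path: str | os.PathLike) -> tuple[np.ndarray, np.ndarray]:
    """Read a 3D NIfTI-1 volume.

    Returns the scaled voxel data (``scl_slope``/``scl_inter`` applied, as
    float64) and the affine. 4D or higher-dimensional images are rejected:
    only 3D volumetric inputs are supported.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"volume not found: {path}")
    img = nib.load(str(path))
    shape = img.shape
    # tolerate trailing singleton dims some writers emit, reject real 4D data
    if len(shape) > 3:
        if any(s != 1 for s in shape[3:]):
            raise ValueError(
                f"expected 3D volume, got shape {shape} in {path}; "
                "4D/time-series images are not supported"
            )
        data = np.asarray(img.get_fdata(), dtype=np.float64).reshape(shape[:3], order="F")
    elif len(shape) < 3:
        raise ValueError(f"expected 3D volume, got shape {shape} in {path}")
    else:
        data = np.asarray(img.get_fdata(), dtype=np.float64)
    return data, np.asarray(img.affine, dtype=float)


def mask_from_array(
    mask: np.ndarray,
    affine: np.ndarray | None = None,
    threshold: float = 0.5,
) -> MaskGeometry:
    """Build a :class:`MaskGeometry` from an in-memory array (value > threshold)."""
    mask = np.asarray(mask)
    if mask.ndim != 3:
        raise ValueError(f"mask must be 3D, got shape {mask.shape}")
    inside = mask > threshold
    if not inside.any():
        raise ValueError("empty mask: no voxel exceeds the threshold")
    idx = np.flatnonzero(inside.ravel(order="F"))
    if affine is None:
        affine = np.eye(4)
    return MaskGeometry(shape=tuple(mask.shape), affine=affine, voxel_index=idx)


def load_mask(path: str | os.PathLike, threshold: float = 0.5) -> MaskGeometry:
    """Load a brain mask; a voxel is in-mask iff its value > ``threshold``.

    The default 0.5 handles both binary and probabilistic masks.
    """
    data, affine = read_volume(path)
    return mask_from_array(data, affine=affine, threshold=threshold)


def stack_cohort(
    paths: Sequence[str | os.PathLike],
    geometry: MaskGeometry,
    subject_ids: Sequence | None = None,
) -> VoxelMatrix:
    """Stack per-subject volumes into an ``n x tau`` :class:`VoxelMatrix`.

    Every volume must live on the mask grid; a mismatching file is named in
    the error. No resampling is ever attempted.
    """
    if len(paths) == 0:
        raise ValueError("stack_cohort requires at least one volume")
    out = np.empty((len(paths), geometry.tau), dtype=np.float64)
    for i, p in enumerate(paths):
        data, affine = read_volume(p)
        if tuple(data.shape) != tuple(geometry.shape):
            raise ValueError(
                f"volume grid mismatch in {p}: shape {data.shape} vs mask "
                f"{geometry.shape}; inputs must share one voxel grid"
            )
        if not np.allclose(affine, geometry.affine, atol=1e-4):
            raise ValueError(
                f"affine mismatch in {p}: volume is not aligned with the mask grid"
            )
        out[i] = data.ravel(order="F")[geometry.voxel_index]
    ids = list(subject_ids) if subject_ids is not None else [str(p) for p in paths]
    return VoxelMatrix(data=out, geometry=geometry, subject_ids=ids)


def scatter_to_volume(
    values: np.ndarray,
    geometry: MaskGeometry,
    background: float = 0.0,
) -> np.ndarray:
    """Scatter a length-tau vector back onto the 3D grid (inverse of stacking)."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size != geometry.tau:
        raise ValueError(
            f"expected {geometry.tau} values (one per in-mask voxel), got {values.size}"
        )
    flat = np.full(int(np.prod(geometry.shape)), background, dtype=np.float64)
    flat[geometry.voxel_index] = values
    return flat.reshape(geometry.shape, order="F")


def write_stat_map(
    values: np.ndarray,
    geometry: MaskGeometry,
    path: str | os.PathLike,
    background: float = 0.0,
) -> None:
    """Write a per-voxel statistic vector as a 3D NIfTI map.

    Out-of-mask voxels get ``background`` (0 by default; NaN selectable) and
    the affine is copied from the mask. Maps are stored as 32-bit float.
    """
    vol = scatter_to_volume(values, geometry, background=background).astype(np.float32)
    img = nib.Nifti1Image(vol, geometry.affine)
    img.header.set_data_dtype(np.float32)
    nib.save(img, str(path))
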