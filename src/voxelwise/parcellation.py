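"""Artificial parcellation: uniform chunking of the masked voxels.

Fitting tens of thousands of independent per-voxel models is embarrassingly
parallel. The masked voxel axis is split into a fixed number of near-uniform
contiguous parcels (default 200) — the "process space" — and per-parcel
workers run serially or on a process-local pool. The contract that matters
is partition invariance: for a deterministic per-voxel worker, results are
identical whatever the parcel count or execution order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from joblib import Parallel, delayed

from .volio import VoxelMatrix

__all__ = ["ParcelMap", "parcellate", "scatter_gather", "ParcelWorkerError"]

DEFAULT_N_PARCELS = 200


@dataclass(frozen=True)
class ParcelMap:
    """Disjoint cover of the tau voxels by contiguous near-uniform parcels."""

    tau: int
    n_parcels: int
    offsets: np.ndarray  # length n_parcels + 1; parcel k spans offsets[k]:offsets[k+1]

    @property
    def sizes(self) -> np.ndarray:
        return np.diff(self.offsets)

    @property
    def assignment(self) -> np.ndarray:
        """Length-tau parcel id per voxel."""
        return np.repeat(np.arange(self.n_parcels), self.sizes)

    def parcel_slice(self, k: int) -> slice:
        return slice(int(self.offsets[k]), int(self.offsets[k + 1]))


def parcellate(tau: int, n_parcels: int = DEFAULT_N_PARCELS) -> ParcelMap:
    """Split ``tau`` voxels into ``n_parcels`` contiguous blocks.

    Sizes are ``floor(tau/P)`` or ``ceil(tau/P)``; exactly ``tau mod P``
    parcels take the larger size. If ``n_parcels > tau`` it is reduced to
    ``tau`` (each parcel gets one voxel) with a warning.
    """
    if tau <= 0:
        raise ValueError("cannot parcellate an empty mask (tau = 0)")
    if n_parcels < 1:
        raise ValueError("n_parcels must be >= 1")
    if n_parcels > tau:
        warnings.warn(
            f"n_parcels={n_parcels} exceeds tau={tau}; reduced to {tau}",
            stacklevel=2,
        )
        n_parcels = tau
    base, rem = divmod(tau, n_parcels)
    sizes = np.full(n_parcels, base, dtype=np.intp)
    sizes[:rem] += 1
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    return ParcelMap(tau=tau, n_parcels=n_parcels, offsets=offsets)


class ParcelWorkerError(RuntimeError):
    """Worker failure, annotated with the parcel id and first voxel index."""


def _run_parcel(worker, data, pm, k):
    sl = pm.parcel_slice(k)
    try:
        return worker(data[:, sl], np.arange(sl.start, sl.stop))
    except Exception as exc:  # noqa: BLE001 - re-raise with parcel context
        raise ParcelWorkerError(
            f"worker failed on parcel {k} (first voxel index {sl.start}): {exc}"
        ) from exc


def scatter_gather(
    matrix: VoxelMatrix | np.ndarray,
    pm: ParcelMap,
    worker: Callable[[np.ndarray, np.ndarray], np.ndarray],
    n_jobs: int = 1,
) -> np.ndarray:
    """Run ``worker(columns, voxel_indices)`` on each parcel; gather in voxel order.

    ``worker`` must be a pure function of its parcel's columns; it may return
    a 1D array (one value per voxel) or a 2D array with one *column* per
    voxel. Outputs are concatenated along the voxel axis, so the result for
    any parcel count equals a single whole-matrix run.
    """
    data = matrix.data if isinstance(matrix, VoxelMatrix) else np.asarray(matrix)
    if data.shape[1] != pm.tau:
        raise ValueError(f"matrix has {data.shape[1]} voxels, parcel map covers {pm.tau}")
    if n_jobs == 1:
        pieces = [_run_parcel(worker, data, pm, k) for k in range(pm.n_parcels)]
    else:
        pieces = Parallel(n_jobs=n_jobs)(
            delayed(_run_parcel)(worker, data, pm, k) for k in range(pm.n_parcels)
        )
    pieces = [np.asarray(p) for p in pieces]
    axis = 0 if pieces[0].ndim == 1 else 1
    return np.concatenate(pieces, axis=axis)
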