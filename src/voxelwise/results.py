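"""Shared result container for per-voxel model fits."""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .volio import MaskGeometry, write_stat_map

__all__ = ["StatMapResult"]


@dataclass
class StatMapResult:
    """Per-term, per-voxel fit outputs, mappable back to 3D.

    All arrays are ``tau x p`` (one row per voxel, one column per design
    column) except ``df_residual``, ``converged`` and ``degenerate`` which
    are length ``tau``. ``stat_name`` is ``"t"`` for Gaussian-theory fits
    and ``"z"`` for Wald statistics from generalized models.
    """

    term_names: list[str]
    beta: np.ndarray
    se: np.ndarray
    stat: np.ndarray
    pvalue: np.ndarray
    df_residual: np.ndarray
    converged: np.ndarray
    degenerate: np.ndarray
    stat_name: str = "t"
    extra: dict = field(default_factory=dict)

    @property
    def tau(self) -> int:
        return self.beta.shape[0]

    @property
    def n_terms(self) -> int:
        return self.beta.shape[1]

    def term_index(self, name: str) -> int:
        try:
            return self.term_names.index(name)
        except ValueError:
            raise KeyError(f"unknown term {name!r}; terms are {self.term_names}") from None

    def term_map(self, name: str, stat: str = "stat") -> np.ndarray:
        """Length-tau vector of one statistic for one term."""
        k = self.term_index(name)
        arrays = {
            "beta": self.beta,
            "se": self.se,
            "stat": self.stat,
            self.stat_name: self.stat,
            "p": self.pvalue,
            "pvalue": self.pvalue,
        }
        if stat not in arrays:
            raise KeyError(f"unknown statistic {stat!r}")
        return arrays[stat][:, k]

    def write_maps(
        self,
        prefix: str | os.PathLike,
        geometry: MaskGeometry,
        background: float = 0.0,
    ) -> list[str]:
        """Write one NIfTI volume per statistic per term: ``<prefix>_<term>_<stat>.nii.gz``."""
        written = []
        stats = {"beta": self.beta, "se": self.se, self.stat_name: self.stat, "p": self.pvalue}
        for k, term in enumerate(self.term_names):
            safe = term.replace(":", "_x_").replace("[", ".").replace("]", "")
            for sname, arr in stats.items():
                path = f"{prefix}_{safe}_{sname}.nii.gz"
                write_stat_map(arr[:, k], geometry, path, background=background)
                written.append(path)
        return written
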