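"""Static ortho-slice rendering of statistic maps."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless rendering only
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["render_ortho"]


def render_ortho(
    volume: np.ndarray,
    out_path: str,
    background: np.ndarray | None = None,
    slices: tuple[int, int, int] | None = None,
    title: str | None = None,
) -> str:
    """Render three orthogonal slices of a 3D map to a PNG.

    Signed maps get a symmetric diverging color scale centered on 0 (so
    positive and negative effects are visually comparable); non-negative
    maps a sequential one. ``slices`` defaults to the volume center.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 3:
        raise ValueError("render_ortho requires a 3D volume")
    if slices is None:
        slices = tuple(s // 2 for s in volume.shape)
    for axis, idx in enumerate(slices):
        if not 0 <= idx < volume.shape[axis]:
            raise ValueError(
                f"slice index {idx} out of range for axis {axis} "
                f"(size {volume.shape[axis]})"
            )
    finite = volume[np.isfinite(volume)]
    vmax = float(np.max(np.abs(finite))) if finite.size else 1.0
    vmax = vmax if vmax > 0 else 1.0
    signed = bool(finite.size) and float(np.min(finite)) < 0
    if signed:
        cmap, vmin = "RdBu_r", -vmax
    else:
        cmap, vmin = "hot", 0.0

    panels = [
        volume[slices[0], :, :],
        volume[:, slices[1], :],
        volume[:, :, slices[2]],
    ]
    bgs = None
    if background is not None:
        background = np.asarray(background, dtype=float)
        if background.shape != volume.shape:
            raise ValueError("background grid does not match the map")
        bgs = [
            background[slices[0], :, :],
            background[:, slices[1], :],
            background[:, :, slices[2]],
        ]

    fig, axes = plt.subplots(1, 3, figsize=(9, 3.2))
    names = ["sagittal (x)", "coronal (y)", "axial (z)"]
    im = None
    for ax, panel, name in zip(axes, panels, names):
        if bgs is not None:
            ax.imshow(bgs.pop(0).T, origin="lower", cmap="gray")
        shown = np.where(panel == 0, np.nan, panel)
        im = ax.imshow(shown.T, origin="lower", cmap=cmap, vmin=vmin, vmax=vmax)
        ax.set_title(name, fontsize=9)
        ax.axis("off")
    cbar = fig.colorbar(im, ax=axes, shrink=0.8)
    cbar.ax.tick_params(labelsize=8)
    if title:
        fig.suptitle(title, fontsize=10)
    fig.savefig(out_path, dpi=110, bbox_inches="tight")
    plt.close(fig)
    return out_path
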