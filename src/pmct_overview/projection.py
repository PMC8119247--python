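"""Orthographic projections of a CT volume.

Collapses the 3D volume along a view axis into 2D HU images:

* MIP — ray maximum; bones and radiopaque material dominate,
* selective minIP — ray minimum over voxels *not* flagged as exterior
  air, so only intracorporeal gas shows,
* average — ray arithmetic mean, resembling a plain radiograph.

View conventions (canonical volume axes x: left->right, y: anterior->
posterior, z: inferior->superior):

* ``anterior_posterior`` collapses y; image rows are z (head up),
  columns are x,
* ``lateral`` collapses x; image rows are z (head up), columns are y.

Rays of the selective minIP in which every voxel is flagged (i.e. pure
exterior air) return the sentinel ``+3071`` HU — the top of the
conventional 12-bit HU range — which is guaranteed above every threshold
so such pixels can never render blue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_ct import CTVolume
from .segmentation import ExteriorAirMask

__all__ = [
    "ProjectionImage",
    "VIEWS",
    "ALL_MASKED_SENTINEL_HU",
    "mip",
    "selective_minip",
    "average_projection",
    "resample_isotropic",
]

VIEWS = ("anterior_posterior", "lateral")

#: HU returned for selective-minIP rays whose voxels are all masked.
ALL_MASKED_SENTINEL_HU = 3071.0


@dataclass(frozen=True)
class ProjectionImage:
    """A 2D HU image produced by collapsing the volume along one axis."""

    values: np.ndarray
    pixel_spacing: tuple[float, float]  # (row, column) mm
    view: str
    kind: str  # mip | minip | average

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64)
        if vals.ndim != 2:
            raise ValueError("projection must be 2D")
        if self.view not in VIEWS:
            raise ValueError(f"unknown view {self.view!r}")
        object.__setattr__(self, "values", vals)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _collapse_axis(view: str) -> int:
    if view == "anterior_posterior":
        return 1
    if view == "lateral":
        return 0
    raise ValueError(f"unknown view {view!r}; expected one of {VIEWS}")


def _orient(collapsed: np.ndarray) -> np.ndarray:
    # after collapsing, axes are (in-plane, z); rows must be z with the
    # superior end at row 0 (head up)
    return collapsed.T[::-1, :].copy()


def _plane_spacing(volume: CTVolume, view: str) -> tuple[float, float]:
    sx, sy, sz = volume.spacing
    return (sz, sx) if view == "anterior_posterior" else (sz, sy)


def mip(volume: CTVolume, view: str) -> ProjectionImage:
    """Maximum intensity projection along the view axis."""
    axis = _collapse_axis(view)
    vals = _orient(volume.voxels.max(axis=axis))
    return ProjectionImage(vals, _plane_spacing(volume, view), view, "mip")


def average_projection(volume: CTVolume, view: str) -> ProjectionImage:
    """Arithmetic-mean projection of the full (unmasked) volume."""
    axis = _collapse_axis(view)
    vals = _orient(volume.voxels.mean(axis=axis, dtype=np.float64))
    return ProjectionImage(vals, _plane_spacing(volume, view), view, "average")


def selective_minip(
    volume: CTVolume, mask: ExteriorAirMask, view: str
) -> ProjectionImage:
    """Minimum intensity projection ignoring exterior-air voxels.

    Masked voxels do not take part in the minimum; rays with every voxel
    masked return :data:`ALL_MASKED_SENTINEL_HU`.
    """
    if mask.flags.shape != volume.shape:
        raise ValueError(
            f"mask shape {mask.flags.shape} != volume shape {volume.shape}"
        )
    axis = _collapse_axis(view)
    shielded = np.where(mask.flags, np.inf, volume.voxels)
    vals = shielded.min(axis=axis)
    vals = np.where(np.isinf(vals), ALL_MASKED_SENTINEL_HU, vals)
    return ProjectionImage(_orient(vals), _plane_spacing(volume, view), view, "minip")


def _resample_axis(a: np.ndarray, spacing: float, target: float, axis: int) -> np.ndarray:
    """Linearly resample one axis from ``spacing`` to ``target`` mm/px."""
    n = a.shape[axis]
    m = int(np.floor((n - 1) * spacing / target)) + 1
    x = np.clip(np.arange(m) * (target / spacing), 0.0, n - 1.0)
    i0 = np.floor(x).astype(np.intp)
    i1 = np.minimum(i0 + 1, n - 1)
    frac = x - i0
    shape = [1, 1]
    shape[axis] = m
    frac = frac.reshape(shape)
    a0 = np.take(a, i0, axis=axis)
    a1 = np.take(a, i1, axis=axis)
    return a0 + (a1 - a0) * frac


def resample_isotropic(image: ProjectionImage) -> ProjectionImage:
    """Resample to square pixels (min of the two spacings), linear interpolation.

    Already-isotropic images are returned unchanged.  Interpolation can
    never leave the input HU range.
    """
    sr, sc = image.pixel_spacing
    if sr == sc:
        return image
    target = min(sr, sc)
    vals = image.values
    if sr != target:
        vals = _resample_axis(vals, sr, target, axis=0)
    if sc != target:
        vals = _resample_axis(vals, sc, target, axis=1)
    return ProjectionImage(vals, (target, target), image.view, image.kind)
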