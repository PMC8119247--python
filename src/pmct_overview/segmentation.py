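"""Exterior-air segmentation by seeded region growing.

The selective minIP must see only gas *inside* the body, so every
low-density voxel connected to the outside — the surrounding air, body
bags, and the hollow air-filled interior of the CT table — has to be
flagged first.  Seeds are the eight volume corners (always outside the
body) plus, optionally, seeds detected inside the hollow table, whose
cavity is not reachable from the corners.

Region growing over a fixed threshold is the connected-component problem:
a voxel is flagged iff its HU is at or below the air threshold and it is
connected (under the configured neighbourhood) to an accepted seed.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .config import AlgorithmConfig
from .io_ct import CTVolume

__all__ = [
    "SeedPoint",
    "ExteriorAirMask",
    "corner_seeds",
    "table_seeds",
    "region_grow_exterior",
    "segment_exterior_air",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SeedPoint:
    """A 0-based voxel index used to start region growing."""

    index: tuple[int, int, int]

    def __iter__(self):
        return iter(self.index)


@dataclass(frozen=True)
class ExteriorAirMask:
    """Boolean mask of voxels absorbed by exterior-air region growing."""

    flags: np.ndarray

    def __post_init__(self) -> None:
        flags = np.asarray(self.flags, dtype=bool)
        if flags.ndim != 3:
            raise ValueError("mask must be 3D")
        object.__setattr__(self, "flags", flags)

    @property
    def voxel_count(self) -> int:
        return int(self.flags.sum())


def corner_seeds(volume: CTVolume) -> list[SeedPoint]:
    """The eight corner voxels of the volume — always outside the body."""
    nx, ny, nz = volume.shape
    return [
        SeedPoint(idx)
        for idx in itertools.product((0, nx - 1), (0, ny - 1), (0, nz - 1))
    ]


def _scan_line(hu_line: np.ndarray, threshold: float, max_shell: int) -> int | None:
    """Scan one line for a thin-shell cavity entry point.

    Skips leading air (HU <= threshold), then a contiguous run of
    above-threshold material of at most ``max_shell`` samples (the table
    shell), and returns the index of the first sub-threshold sample after
    it.  Returns None when no shell is crossed or the run is too thick to
    be a table shell (e.g. the body wall).
    """
    n = len(hu_line)
    i = 0
    while i < n and hu_line[i] <= threshold:
        i += 1
    if i == 0 or i == n:
        return None  # started on material, or pure air
    run_start = i
    while i < n and hu_line[i] > threshold:
        i += 1
    if i == n or (i - run_start) > max_shell:
        return None
    return i


def table_seeds(volume: CTVolume, config: AlgorithmConfig) -> list[SeedPoint]:
    """Detect seeds inside a hollow, air-filled CT table.

    On every axial slice, the central column is scanned upward from the
    posterior image border: leading background air is skipped, then the
    first thin run of above-threshold material (the table shell); the
    first sub-threshold voxel behind it lies in the table cavity and
    becomes a seed.  The scan is then repeated inward from the left and
    right image borders at the height of the detected cavity.

    Two guards keep the scan from misreading anatomy as a table: runs of
    material thicker than ``config.table_shell_max_mm`` (the body wall, a
    solid table) abort the scan, and the bottom scan only searches the
    posterior ``config.table_search_band_frac`` of the image, where the
    table physically sits.  Bodies without a hollow table therefore yield
    no seeds.
    """
    nx, ny, nz = volume.shape
    sx, sy, _ = volume.spacing
    thr = config.air_threshold_hu
    seeds: list[SeedPoint] = []
    xc = nx // 2
    band = max(2, int(round(config.table_search_band_frac * ny)))
    for k in range(nz):
        # upward from the posterior (bottom) border along the central column,
        # restricted to the posterior band where the table sits
        col = volume.voxels[xc, : ny - 1 - band : -1, k]  # posterior -> anterior
        max_shell_y = max(1, int(config.table_shell_max_mm / sy))
        hit = _scan_line(col, thr, max_shell_y)
        if hit is None:
            continue
        jy = ny - 1 - hit
        seeds.append(SeedPoint((xc, jy, k)))
        # inward from the left and right borders at the cavity's height
        max_shell_x = max(1, int(config.table_shell_max_mm / sx))
        row = volume.voxels[:, jy, k]
        left = _scan_line(row, thr, max_shell_x)
        if left is not None:
            seeds.append(SeedPoint((left, jy, k)))
        right = _scan_line(row[::-1], thr, max_shell_x)
        if right is not None:
            seeds.append(SeedPoint((nx - 1 - right, jy, k)))
    return seeds


def region_grow_exterior(
    volume: CTVolume,
    seeds: list[SeedPoint],
    config: AlgorithmConfig | None = None,
) -> ExteriorAirMask:
    """Flag every air voxel connected to an accepted seed.

    A voxel is flagged iff its HU is at or below ``config.air_threshold_hu``
    (inclusive) and it lies in the same connected component, under
    ``config.connectivity``, as a seed that itself satisfies the threshold.
    Seeds on above-threshold voxels are silently skipped; never flags a
    voxel above the threshold.
    """
    config = config or AlgorithmConfig()
    air = volume.voxels <= config.air_threshold_hu
    if not seeds:
        log.warning("region growing called with no seeds; returning empty mask")
        return ExteriorAirMask(np.zeros(volume.shape, dtype=bool))

    order = 1 if config.connectivity == "face" else 3
    structure = ndi.generate_binary_structure(3, order)
    labels, _ = ndi.label(air, structure=structure)
    accepted = {int(labels[tuple(s)]) for s in seeds if air[tuple(s)]}
    accepted.discard(0)
    if not accepted:
        log.warning("no seed fell on an air voxel; mask is empty")
        return ExteriorAirMask(np.zeros(volume.shape, dtype=bool))
    mask = np.isin(labels, sorted(accepted))
    return ExteriorAirMask(mask)


def segment_exterior_air(
    volume: CTVolume, config: AlgorithmConfig | None = None
) -> tuple[ExteriorAirMask, list[SeedPoint], list[SeedPoint]]:
    """Full seeding + region growing step.

    Returns the mask together with the corner and table seed lists.
    """
    config = config or AlgorithmConfig()
    corners = corner_seeds(volume)
    table = table_seeds(volume, config) if config.table_seeds_enabled else []
    mask = region_grow_exterior(volume, corners + table, config)
    return mask, corners, table
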