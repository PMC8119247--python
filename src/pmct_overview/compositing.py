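"""Rule-based compositing of the three projections into one RGB image.

For every pixel, in order:

1. gray level = window(0.7 * MIP_HU + 0.3 * AVG_HU) -> (g, g, g),
2. if MIP_HU > 2800: the pixel is pure red (radiopaque material),
3. if minIP_HU < -220: the pixel is pure blue (intracorporeal gas).

The rules are applied sequentially, so blue overrides red where both
fire.  Both color thresholds are strict inequalities: the threshold
values themselves never trigger color.  The blend of rule 1 is computed
in HU and windowed once for display (default center 500 HU, width
1000 HU); display levels round half-up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import AlgorithmConfig
from .io_ct import CompositeImage
from .projection import ProjectionImage

__all__ = ["WindowMapping", "apply_window", "composite"]


@dataclass(frozen=True)
class WindowMapping:
    """Clamped linear HU -> display-level mapping (center/width, HU)."""

    center_hu: float
    width_hu: float

    def __post_init__(self) -> None:
        if self.width_hu <= 0:
            raise ValueError("window width must be positive")

    @property
    def lower_hu(self) -> float:
        return self.center_hu - self.width_hu / 2.0

    @property
    def upper_hu(self) -> float:
        return self.center_hu + self.width_hu / 2.0


def apply_window(value, window: WindowMapping):
    """Map HU to 8-bit display levels: clamp, linear ramp, round half-up.

    HU at or below ``center - width/2`` map to 0, at or above
    ``center + width/2`` to 255.  Accepts scalars or arrays.
    """
    arr = np.asarray(value, dtype=np.float64)
    frac = np.clip((arr - window.lower_hu) / window.width_hu, 0.0, 1.0)
    levels = np.floor(frac * 255.0 + 0.5).astype(np.uint8)
    return levels if arr.ndim else int(levels)


def composite(
    mip_img: ProjectionImage,
    minip_img: ProjectionImage,
    avg_img: ProjectionImage,
    config: AlgorithmConfig | None = None,
) -> CompositeImage:
    """Apply the three pixel rules to aligned MIP / minIP / average images."""
    config = config or AlgorithmConfig()
    if not (mip_img.view == minip_img.view == avg_img.view):
        raise ValueError(
            "view mismatch: "
            f"{mip_img.view} / {minip_img.view} / {avg_img.view}"
        )
    if not (mip_img.shape == minip_img.shape == avg_img.shape):
        raise ValueError(
            "shape mismatch: "
            f"{mip_img.shape} / {minip_img.shape} / {avg_img.shape}"
        )

    window = WindowMapping(config.window_center_hu, config.window_width_hu)
    blend_hu = config.mip_weight * mip_img.values + config.avg_weight * avg_img.values
    gray = apply_window(blend_hu, window)
    rgb = np.repeat(gray[:, :, None], 3, axis=2)

    red = mip_img.values > config.red_threshold_hu
    rgb[red] = (255, 0, 0)
    blue = minip_img.values < config.blue_threshold_hu
    rgb[blue] = (0, 0, 255)

    return CompositeImage(rgb, mip_img.pixel_spacing, mip_img.view)
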