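"""End-to-end pipeline: load -> segment -> project -> composite -> export.

The exterior-air mask is computed once and shared by the anterior-
posterior and lateral views; per view, the MIP, selective minIP and
average projections are resampled to isotropic pixels and composited
into one PNG.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .compositing import composite
from .config import AlgorithmConfig
from .io_ct import CTVolume, read_dicom_series, read_nifti, write_nifti, write_png
from .projection import (
    VIEWS,
    average_projection,
    mip,
    resample_isotropic,
    selective_minip,
)
from .segmentation import segment_exterior_air

__all__ = ["RunReport", "load_volume", "render_views", "run_pipeline"]

log = logging.getLogger(__name__)

_VIEW_ALIASES = {
    "ap": "anterior_posterior",
    "anterior_posterior": "anterior_posterior",
    "lateral": "lateral",
}


@dataclass
class RunReport:
    """Summary of one pipeline run."""

    input_path: str
    views_rendered: list[str] = field(default_factory=list)
    corner_seed_count: int = 0
    table_seed_count: int = 0
    mask_voxel_count: int = 0
    output_files: list[str] = field(default_factory=list)
    elapsed_seconds: float = 0.0


def normalize_view(name: str) -> str:
    try:
        return _VIEW_ALIASES[name.strip().lower()]
    except KeyError:
        raise ValueError(
            f"unknown view {name!r}; expected one of ap, anterior_posterior, lateral"
        ) from None


def load_volume(input_path: str | Path) -> CTVolume:
    """Load a CT volume from a DICOM series directory or a NIfTI file."""
    p = Path(input_path)
    if p.is_dir():
        return read_dicom_series(p)
    return read_nifti(p)


def render_views(
    volume: CTVolume,
    config: AlgorithmConfig | None = None,
    views: tuple[str, ...] = VIEWS,
):
    """Segment once, then yield ``(view, CompositeImage)`` per requested view."""
    config = config or AlgorithmConfig()
    mask, corners, table = segment_exterior_air(volume, config)
    images = {}
    for view in views:
        proj_mip = resample_isotropic(mip(volume, view))
        proj_min = resample_isotropic(selective_minip(volume, mask, view))
        proj_avg = resample_isotropic(average_projection(volume, view))
        images[view] = composite(proj_mip, proj_min, proj_avg, config)
    return images, mask, corners, table


def run_pipeline(
    input_path: str | Path,
    output_dir: str | Path,
    config: AlgorithmConfig | None = None,
    views: tuple[str, ...] = ("anterior_posterior", "lateral"),
    save_mask: bool = False,
    save_projections: bool = False,
) -> RunReport:
    """Render the requested overview views of one CT dataset to PNG files.

    Writes ``<stem>_<view>.png`` per view into ``output_dir``; the
    exterior mask is computed once and shared by all views.
    """
    t0 = time.perf_counter()
    config = config or AlgorithmConfig()
    views = tuple(normalize_view(v) for v in views)
    if not views:
        raise ValueError("no views requested")

    input_path = Path(input_path)
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    stem = input_path.name.removesuffix(".gz").rsplit(".", 1)[0]

    volume = load_volume(input_path)
    log.info("loaded %s: shape=%s spacing=%s", input_path, volume.shape, volume.spacing)

    images, mask, corners, table = render_views(volume, config, views)
    log.info(
        "segmentation: %d corner seeds, %d table seeds, %d voxels flagged",
        len(corners), len(table), mask.voxel_count,
    )

    report = RunReport(
        input_path=str(input_path),
        corner_seed_count=len(corners),
        table_seed_count=len(table),
        mask_voxel_count=mask.voxel_count,
    )
    if save_mask:
        mask_path = output_dir / f"{stem}_exterior_mask.nii.gz"
        write_nifti(
            CTVolume(mask.flags.astype(np.float32) + 0.0, volume.spacing, volume.origin),
            mask_path,
        )
        report.output_files.append(str(mask_path))
    for view, image in images.items():
        out = output_dir / f"{stem}_{view}.png"
        write_png(image, out)
        log.debug(
            "%s: %dx%d px, %d red, %d blue",
            view,
            image.pixels.shape[1],
            image.pixels.shape[0],
            int(((image.pixels == (255, 0, 0)).all(axis=2)).sum()),
            int(((image.pixels == (0, 0, 255)).all(axis=2)).sum()),
        )
        if save_projections:
            for kind, proj in (
                ("mip", mip(volume, view)),
                ("minip", selective_minip(volume, mask, view)),
                ("average", average_projection(volume, view)),
            ):
                np.savetxt(
                    output_dir / f"{stem}_{view}_{kind}.txt",
                    proj.values,
                    fmt="%.3f",
                )
        report.views_rendered.append(view)
        report.output_files.append(str(out))
    report.elapsed_seconds = time.perf_counter() - t0
    return report
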