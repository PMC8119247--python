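"""Algorithm configuration.

All tunable constants of the overview-image algorithm live here, with the
published values as defaults:

* exterior air is any voxel at or below ``air_threshold_hu`` (-200 HU)
  connected to a seed outside the body,
* a pixel turns red when the MIP exceeds ``red_threshold_hu`` (2800 HU),
* a pixel turns blue when the selective minIP falls below
  ``blue_threshold_hu`` (-220 HU),
* the gray background blends MIP and average projection 0.7 / 0.3 and is
  windowed at center 500 HU / width 1000 HU.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

__all__ = ["AlgorithmConfig", "ConfigError"]

#: Accepted neighbourhood definitions for region growing.
_CONNECTIVITIES = ("face", "face+edge+corner")


class ConfigError(ValueError):
    """Raised for an invalid configuration value or config file."""


@dataclass(frozen=True)
class AlgorithmConfig:
    """All tunable constants of the overview algorithm.

    Parameters
    ----------
    air_threshold_hu
        Region growing absorbs voxels with HU at or below this value (HU).
    red_threshold_hu
        MIP pixels strictly above this value render red (HU).
    blue_threshold_hu
        Selective-minIP pixels strictly below this value render blue (HU).
    mip_weight, avg_weight
        Blend weights of MIP and average projection for the gray channel;
        must sum to 1.
    window_center_hu, window_width_hu
        Display window applied to the blended HU value.
    table_seeds_enabled
        Whether to search for seeds inside a hollow, air-filled CT table.
    connectivity
        ``"face"`` (6-neighbourhood) or ``"face+edge+corner"``
        (26-neighbourhood) for region growing.
    table_shell_max_mm
        A run of above-threshold material thicker than this is not treated
        as a table shell during seed scanning (mm).  Distinguishes the thin
        table shell from the body wall.
    table_search_band_frac
        Fraction of the image height, measured from the posterior border,
        within which the table shell is searched.  The CT table always sits
        against the posterior border; restricting the scan keeps thin
        tissue slivers elsewhere from being mistaken for a table shell.
    """

    air_threshold_hu: float = -200.0
    red_threshold_hu: float = 2800.0
    blue_threshold_hu: float = -220.0
    mip_weight: float = 0.7
    avg_weight: float = 0.3
    window_center_hu: float = 500.0
    window_width_hu: float = 1000.0
    table_seeds_enabled: bool = True
    connectivity: str = "face"
    table_shell_max_mm: float = 10.0
    table_search_band_frac: float = 0.3

    def __post_init__(self) -> None:
        if abs(self.mip_weight + self.avg_weight - 1.0) > 1e-9:
            raise ConfigError(
                f"mip_weight + avg_weight must equal 1, got "
                f"{self.mip_weight} + {self.avg_weight}"
            )
        if self.window_width_hu <= 0:
            raise ConfigError("window_width_hu must be positive")
        if not (self.blue_threshold_hu < 0 < self.red_threshold_hu):
            raise ConfigError(
                "expected blue_threshold_hu < 0 < red_threshold_hu, got "
                f"{self.blue_threshold_hu} / {self.red_threshold_hu}"
            )
        if self.connectivity not in _CONNECTIVITIES:
            raise ConfigError(
                f"connectivity must be one of {_CONNECTIVITIES}, "
                f"got {self.connectivity!r}"
            )
        if self.table_shell_max_mm <= 0:
            raise ConfigError("table_shell_max_mm must be positive")
        if not (0 < self.table_search_band_frac <= 1):
            raise ConfigError("table_search_band_frac must be in (0, 1]")

    def replace(self, **changes) -> "AlgorithmConfig":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "AlgorithmConfig":
        """Load a config from a flat ``key = value`` text file.

        Blank lines and lines starting with ``#`` are ignored.  Keyword
        ``overrides`` win over file values, file values over defaults.
        """
        values: dict[str, object] = {}
        field_types = {f.name: f.type for f in dataclasses.fields(cls)}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
            key, _, val = (s.strip() for s in line.partition("="))
            if key not in field_types:
                raise ConfigError(f"{path}:{lineno}: unknown key {key!r}")
            values[key] = _parse_value(key, val)
        values.update(overrides)
        return cls(**values)

    def to_file(self, path: str | Path) -> None:
        """Write the config as a flat ``key = value`` file."""
        lines = [
            f"{f.name} = {getattr(self, f.name)}"
            for f in dataclasses.fields(self)
        ]
        Path(path).write_text("\n".join(lines) + "\n")


def _parse_value(key: str, val: str) -> object:
    if key == "connectivity":
        return val
    if key == "table_seeds_enabled":
        low = val.lower()
        if low in ("true", "1", "yes", "on"):
            return True
        if low in ("false", "0", "no", "off"):
            return False
        raise ConfigError(f"cannot parse boolean {val!r} for {key}")
    try:
        return float(val)
    except ValueError as exc:
        raise ConfigError(f"cannot parse number {val!r} for {key}") from exc
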