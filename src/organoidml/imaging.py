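"""Calibrated image I/O: z-stacks, maximum projections, plate metadata.

The assay images each well as a brightfield z-stack (optionally with a
co-registered far-red fluorescence channel for the vital dye).  All
downstream analysis runs on the per-pixel maximum projection of the stack.
Pixel indices are 0-based ``(row, column)``, row-major; physical position in
micrometres is ``index * pixel_size_um``.  Intensities are converted to
float64 on load with no rescaling.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import FormatError, ParameterError, SchemaError, ValidationError

BRIGHTFIELD = "brightfield"
FLUORESCENCE = "fluorescence"

_CONTROL_VALUES = {"negative", "positive", "treated"}

PLATE_MAP_COLUMNS = ["well", "pdo", "treatment", "dose", "unit", "group", "control"]


@dataclass
class Image2D:
    """A single calibrated 2D intensity image (e.g. a maximum projection)."""

    pixels: np.ndarray
    pixel_size_um: float
    channel: str = BRIGHTFIELD
    well: str | None = None
    field: int = 0
    timepoint_day: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValidationError("Image2D requires a 2D pixel array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValidationError("Image2D intensities must be finite")
        if np.any(self.pixels < 0):
            raise ValidationError("Image2D intensities must be non-negative")
        if self.pixel_size_um <= 0:
            raise ParameterError("pixel_size_um must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class ImageStack:
    """An ordered z-stack of same-shape planes with physical z calibration."""

    planes: np.ndarray  # (n_planes, H, W) float64
    pixel_size_um: float
    z_start_um: float = 0.0
    z_step_um: float = 1.0
    channel: str = BRIGHTFIELD
    well: str | None = None
    field: int = 0
    timepoint_day: float | None = None

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes, dtype=np.float64)
        if self.planes.ndim != 3 or self.planes.shape[0] < 1:
            raise ValidationError("ImageStack requires >= 1 plane of equal shape")
        if self.z_step_um <= 0:
            raise ParameterError("z_step_um must be > 0")
        if self.pixel_size_um <= 0:
            raise ParameterError("pixel_size_um must be > 0")

    @property
    def n_planes(self) -> int:
        return self.planes.shape[0]

    def plane_depth_um(self, k: int) -> float:
        """Physical depth of plane ``k`` (0-based page order)."""
        if not 0 <= k < self.n_planes:
            raise IndexError(f"plane index {k} out of range")
        return self.z_start_um + k * self.z_step_um


def load_stack(
    path: str | Path,
    *,
    pixel_size_um: float,
    z_start_um: float = 0.0,
    z_step_um: float = 1.0,
    channel: str = BRIGHTFIELD,
    well: str | None = None,
    field: int = 0,
    timepoint_day: float | None = None,
) -> ImageStack:
    """Read a single- or multi-page TIFF into an :class:`ImageStack`.

    Pages are kept in stored order (page k at depth ``z_start + k*z_step``).
    Calibration comes from the caller (typically the run config), which
    overrides whatever the instrument wrote into the TIFF tags — exports are
    too inconsistent to trust.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            pages = []
            for page in tif.pages:
                arr = page.asarray()
                if arr.ndim == 3:  # volumetric page: leading axis is z
                    pages.extend(arr)
                else:
                    pages.append(arr)
    except (OSError, tifffile.TiffFileError) as exc:
        raise OSError(f"cannot read TIFF stack at {path}: {exc}") from exc
    if not pages:
        raise FormatError(f"{path} contains no image pages")
    shapes = {p.shape for p in pages}
    if len(shapes) != 1:
        raise FormatError(f"{path}: inconsistent page shapes {sorted(shapes)}")
    planes = np.stack([np.asarray(p, dtype=np.float64) for p in pages])
    return ImageStack(
        planes=planes,
        pixel_size_um=pixel_size_um,
        z_start_um=z_start_um,
        z_step_um=z_step_um,
        channel=channel,
        well=well,
        field=field,
        timepoint_day=timepoint_day,
    )


def max_project(stack: ImageStack) -> Image2D:
    """Collapse a z-stack to its per-pixel maximum intensity projection."""
    pixels = stack.planes.max(axis=0)
    return Image2D(
        pixels=pixels,
        pixel_size_um=stack.pixel_size_um,
        channel=stack.channel,
        well=stack.well,
        field=stack.field,
        timepoint_day=stack.timepoint_day,
    )


@dataclass
class PlateLayout:
    """Plate map: well → PDO line, treatment, dose and replicate group."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PLATE_MAP_COLUMNS if c not in self.table.columns]
        if missing:
            raise SchemaError(f"plate map missing required columns: {missing}")
        dup = self.table["well"][self.table["well"].duplicated()].tolist()
        if dup:
            raise ValidationError(f"duplicate wells in plate map: {sorted(set(dup))}")
        if len(self.table) and (self.table["dose"].astype(float) < 0).any():
            bad = self.table.loc[self.table["dose"].astype(float) < 0, "well"].tolist()
            raise ValidationError(f"negative dose for wells: {bad}")
        unknown = set(self.table["control"]) - _CONTROL_VALUES
        if unknown:
            raise ValidationError(
                f"control flags must be one of {sorted(_CONTROL_VALUES)}, got {sorted(unknown)}"
            )

    @property
    def wells(self) -> list[str]:
        return self.table["well"].tolist()

    def row(self, well: str) -> pd.Series:
        match = self.table[self.table["well"] == well]
        if match.empty:
            raise KeyError(f"well {well!r} not in plate map")
        return match.iloc[0]

    def replicate_wells(self, group: str) -> list[str]:
        return self.table.loc[self.table["group"] == group, "well"].tolist()


def load_plate_map(path: str | Path) -> PlateLayout:
    """Load and validate a plate-map CSV (``well,pdo,treatment,dose,unit,group,control``).

    Unknown extra columns are preserved as opaque metadata.
    """
    table = pd.read_csv(path, dtype={"well": str, "pdo": str})
    return PlateLayout(table=table)


@dataclass
class Schedule:
    """Imaging schedule in days; media-refresh days are metadata only."""

    days: Sequence[float]
    media_refresh_days: Sequence[float] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        days = list(self.days)
        if not days or days[0] != 0:
            raise ValidationError("schedule must start at day 0")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValidationError("schedule days must be strictly increasing")
        self.days = tuple(days)
        self.media_refresh_days = tuple(self.media_refresh_days)


@dataclass
class RunConfig:
    """Acquisition geometry and on-disk layout for one imaging run."""

    pixel_size_um: float
    z_start_um: float = 0.0
    z_step_um: float = 20.0
    filename_template: str = "{well}_{field}_d{day}_{channel}.tif"
    days: Sequence[float] = (0, 1, 3, 7)

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0 or self.z_step_um <= 0:
            raise ParameterError("pixel_size_um and z_step_um must be > 0")

    def stack_path(self, root: str | Path, well: str, field: int, day, channel: str) -> Path:
        name = self.filename_template.format(well=well, field=field, day=day, channel=channel)
        return Path(root) / name


def load_run_config(path: str | Path) -> RunConfig:
    """Read a YAML run config (keys: pixel_size_um, z_start_um, z_step_um,
    filename_template, days)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {k: raw[k] for k in ("pixel_size_um", "z_start_um", "z_step_um",
                                 "filename_template", "days") if k in raw}
    if "pixel_size_um" not in known:
        raise SchemaError("run config must define pixel_size_um")
    return RunConfig(**known)


def discover_stacks(
    root: str | Path, config: RunConfig, channel: str = BRIGHTFIELD
) -> Iterator[tuple[str, int, float, Path]]:
    """Yield ``(well, field, day, path)`` for files matching the filename template."""
    pattern = re.escape(config.filename_template)
    pattern = (
        pattern.replace(re.escape("{well}"), r"(?P<well>[A-Za-z0-9]+)")
        .replace(re.escape("{field}"), r"(?P<field>\d+)")
        .replace(re.escape("{day}"), r"(?P<day>[0-9.]+)")
        .replace(re.escape("{channel}"), re.escape(channel))
    )
    rx = re.compile(pattern + r"$")
    for path in sorted(Path(root).iterdir()):
        m = rx.match(path.name)
        if m:
            yield m.group("well"), int(m.group("field")), float(m.group("day")), path
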