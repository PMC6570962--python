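"""Image discovery, loading, calibration, and CSV reporting.

Input images are colour rasters (JPEG/PNG/TIFF) of submerged fungal
cultures photographed light-on-dark. Discovery walks an input root of
arbitrary nesting and groups files by their immediate sub-directory, so
that per-sub-directory raw CSVs and quality-control overlays can be
written next to a mirror of each source folder. All physical quantities
are calibrated through a single µm-per-pixel ratio.
"""
from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import ConfigurationError, ImageIOError, NoInputError, ValidationError

logger = logging.getLogger(__name__)

#: Columns of the per-sub-directory raw CSV, one row per particle.
RAW_COLUMNS = [
    "index",
    "image",
    "class",
    "area_um2",
    "feret_max_um",
    "feret_min_um",
    "aspect_ratio",
    "solidity",
    "morphology_number",
]

#: Parameter tables written at the input-root level, one per descriptor
#: per analysed class. "diameter" is the maximum Feret diameter in µm.
PARAMETER_COLUMNS = {
    "diameter": "feret_max_um",
    "area": "area_um2",
    "aspect_ratio": "aspect_ratio",
    "solidity": "solidity",
    "morphology_number": "morphology_number",
}

# Columns in physical units are printed with 2 decimals, dimensionless
# descriptors with 4 (stable CSV diffs across platforms).
_PRECISION = {
    "area_um2": 2,
    "feret_max_um": 2,
    "feret_min_um": 2,
    "aspect_ratio": 4,
    "solidity": 4,
    "morphology_number": 4,
    "value": None,  # decided per parameter table
    "pellet_fraction_pct": 4,
}


@dataclass(frozen=True)
class Calibration:
    """Physical length of one pixel edge, in µm/pixel."""

    um_per_px: float

    def __post_init__(self) -> None:
        if not (self.um_per_px > 0) or not math.isfinite(self.um_per_px):
            raise ConfigurationError(
                f"um_per_px must be a positive finite number, got {self.um_per_px!r}"
            )

    @property
    def area_factor(self) -> float:
        """µm² per pixel: exactly um_per_px squared."""
        return self.um_per_px * self.um_per_px

    def length_um(self, pixels: float) -> float:
        return pixels * self.um_per_px

    def area_um2(self, pixel_count: float) -> float:
        return pixel_count * self.area_factor


@dataclass
class ImageRecord:
    """One loaded image: an 8-bit RGB raster plus its provenance."""

    path: Path
    subdir: str
    raster: np.ndarray

    def __post_init__(self) -> None:
        r = self.raster
        if r.ndim != 3 or r.shape[2] != 3 or r.shape[0] < 1 or r.shape[1] < 1:
            raise ImageIOError(f"{self.path}: expected a non-empty RGB raster, got shape {r.shape}")
        if r.dtype != np.uint8:
            raise ImageIOError(f"{self.path}: expected 8-bit raster, got dtype {r.dtype}")


@dataclass
class ClassificationConfig:
    """Area cut-offs (µm²) separating pellet / dispersed / artefact.

    Defaults follow the 10× magnification profile: pellets are particles
    with area ≥ 500 µm², dispersed mycelium lies in [95, 500) µm², and
    anything below 95 µm² is an imaging artefact excluded from analysis.
    At higher magnification the lower bound can be reduced (e.g. 20 µm²
    at 50×).
    """

    pellet_min_area: float = 500.0
    dispersed_min_area: float = 95.0
    mode: str = "both"

    def __post_init__(self) -> None:
        if not (0 < self.dispersed_min_area < self.pellet_min_area):
            raise ConfigurationError(
                "require 0 < dispersed_min_area < pellet_min_area, got "
                f"{self.dispersed_min_area} / {self.pellet_min_area}"
            )
        if self.mode not in ("pellets", "dispersed", "both"):
            raise ConfigurationError(f"mode must be pellets|dispersed|both, got {self.mode!r}")

    @property
    def analysed_classes(self) -> tuple[str, ...]:
        if self.mode == "both":
            return ("pellet", "dispersed")
        return ("pellet",) if self.mode == "pellets" else ("dispersed",)


@dataclass
class RunConfig:
    """Full parameterisation of one pipeline run."""

    input_root: Path
    output_root: Path
    calibration: Calibration
    suffix: str = "png"
    class_config: ClassificationConfig = field(default_factory=ClassificationConfig)
    threshold_spec: int | str = "isodata"
    connectivity: int = 8
    border_policy: str = "exclude_all"
    contrast_saturation: float = 0.05
    qc_flags: Path | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.input_root = Path(self.input_root)
        self.output_root = Path(self.output_root)
        if self.connectivity not in (4, 8):
            raise ConfigurationError(f"connectivity must be 4 or 8, got {self.connectivity}")
        if self.border_policy not in ("exclude_all", "keep_all"):
            raise ConfigurationError(f"unknown border policy {self.border_policy!r}")
        if not (0 <= self.contrast_saturation < 1):
            raise ConfigurationError(
                f"contrast_saturation must be in [0, 1), got {self.contrast_saturation}"
            )

    @property
    def mode(self) -> str:
        return self.class_config.mode


def _normalise_suffix(suffix: str) -> str:
    return suffix.lower().lstrip(".")


def discover_images(input_root: Path | str, suffix: str) -> dict[str, list[Path]]:
    """Find every image under ``input_root`` whose name ends with ``suffix``.

    Matching is case-insensitive. Files are grouped by their immediate
    containing sub-directory (path relative to the root, ``"."`` for files
    directly in the root) and ordered lexicographically within each group,
    so particle indices are reproducible across runs.
    """
    root = Path(input_root)
    if not root.is_dir():
        raise ConfigurationError(f"input root {root} does not exist or is not a directory")
    ext = "." + _normalise_suffix(suffix)
    groups: dict[str, list[Path]] = {}
    for dirpath, dirnames, filenames in os.walk(root):
        dirnames.sort()
        rel = Path(dirpath).relative_to(root).as_posix()
        matches = sorted(f for f in filenames if f.lower().endswith(ext))
        if matches:
            groups[rel] = [Path(dirpath) / f for f in matches]
    if not groups:
        raise NoInputError(f"no files matching suffix {suffix!r} found under {root}")
    return dict(sorted(groups.items()))


def load_image(path: Path | str, subdir: str = ".") -> ImageRecord:
    """Load a JPEG/PNG/TIFF file as an 8-bit RGB :class:`ImageRecord`.

    Greyscale sources are replicated across the three channels; an alpha
    channel, if present, is dropped.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # imageio raises various backend errors
        raise ImageIOError(f"cannot decode image file {path}: {exc}") from exc
    if arr.size == 0:
        raise ImageIOError(f"{path}: zero-sized raster")
    if arr.dtype != np.uint8:
        # 16-bit TIFFs etc.: rescale into 8 bits
        arr = arr.astype(np.float64)
        hi = arr.max()
        arr = (arr / hi * 255.0).round().astype(np.uint8) if hi > 0 else arr.astype(np.uint8)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] >= 3:
        arr = arr[:, :, :3]
    else:
        raise ImageIOError(f"{path}: unsupported raster shape {arr.shape}")
    return ImageRecord(path=path, subdir=subdir, raster=np.ascontiguousarray(arr))


def _round_cols(df: pd.DataFrame, cols: Iterable[str]) -> pd.DataFrame:
    df = df.copy()
    for c in cols:
        p = _PRECISION.get(c)
        if p is not None and c in df.columns:
            df[c] = df[c].astype(float).round(p)
    return df


def _write_csv(df: pd.DataFrame, path: Path) -> Path:
    try:
        path.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(path, index=False, lineterminator="\n")
    except OSError as exc:
        raise ImageIOError(f"cannot write CSV {path}: {exc}") from exc
    return path


def write_raw_csv(output_dir: Path | str, subdir: str, rows: Sequence[Mapping]) -> Path:
    """Write one raw-measurement CSV for a sub-directory.

    Rows are ordered by (image, particle index) ascending so CSV row order
    matches the numbering on the QC overlays.
    """
    out_dir = Path(output_dir) / subdir if subdir != "." else Path(output_dir)
    df = pd.DataFrame(list(rows), columns=RAW_COLUMNS)
    if len(df):
        df = df.sort_values(["image", "index"], kind="stable").reset_index(drop=True)
    df = _round_cols(df, RAW_COLUMNS)
    return _write_csv(df, out_dir / "raw_data.csv")


def write_parameter_tables(
    output_root: Path | str, rows: Sequence[Mapping], classes: Sequence[str]
) -> dict[str, Path]:
    """Write root-level per-parameter tables, one CSV per descriptor per class.

    Every particle of an analysed class appears exactly once in each of that
    class's five tables (diameter, area, aspect ratio, solidity, MN).
    """
    root = Path(output_root)
    df = pd.DataFrame(list(rows), columns=RAW_COLUMNS + ["subdir"])
    written: dict[str, Path] = {}
    for cls in classes:
        sub = df[df["class"] == cls] if len(df) else df
        for param, col in PARAMETER_COLUMNS.items():
            table = sub[["subdir", "image", "index", col]].rename(columns={col: param})
            prec = _PRECISION.get(col)
            if prec is not None and len(table):
                table[param] = table[param].astype(float).round(prec)
            name = f"{cls}_{param}.csv"
            written[name] = _write_csv(table, root / name)
    return written


def write_pellet_fraction_csv(
    output_root: Path | str, per_subdir_fractions: Mapping[str, float]
) -> Path:
    """Write the single pelleted-fraction CSV covering every sub-directory.

    Fractions are percentages of total fungal area contributed by pellets;
    NaN marks a sub-directory with zero total fungal area (undefined).
    """
    for sub, frac in per_subdir_fractions.items():
        if not math.isnan(frac) and not (0.0 <= frac <= 100.0):
            raise ValidationError(f"pellet fraction for {sub!r} outside [0, 100]: {frac}")
    df = pd.DataFrame(
        {
            "subdir": list(per_subdir_fractions.keys()),
            "pellet_fraction_pct": [float(v) for v in per_subdir_fractions.values()],
        }
    )
    df = _round_cols(df, ["pellet_fraction_pct"])
    return _write_csv(df, Path(output_root) / "pellet_fraction.csv")
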