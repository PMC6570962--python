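"""Size-based classification, heterogeneity statistics, and QC reporting.

Particles are classified purely by calibrated area: pellets at or above
the pellet cut-off, dispersed mycelium between the artefact and pellet
cut-offs, artefacts below the lower bound (logged and excluded from every
analysis and output). Both lower bounds are inclusive and the comparison
is exact — no floating-point slop at the boundaries.

Culture heterogeneity is summarised per directory as the pelleted
fraction: the percentage of total fungal area (pellets + dispersed,
pooled over all images of the directory) contributed by pellets.
"""
from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from PIL import Image, ImageDraw, ImageFont

from .errors import ImageIOError, ValidationError
from .imaging_io import ClassificationConfig, ImageRecord
from .segmentation import Particle
from .shape_metrics import ParticleMetrics

logger = logging.getLogger(__name__)

RED = (255, 0, 0)


def classify(metrics: ParticleMetrics | float, config: ClassificationConfig) -> str:
    """Map a particle (or a bare area in µm²) to pellet/dispersed/artefact."""
    area = metrics.area if isinstance(metrics, ParticleMetrics) else float(metrics)
    if area >= config.pellet_min_area:
        return "pellet"
    if area >= config.dispersed_min_area:
        return "dispersed"
    return "artefact"


def classify_all(
    metrics: Sequence[ParticleMetrics], config: ClassificationConfig
) -> list[ParticleMetrics]:
    """Label every particle; artefacts keep their label for logging only."""
    return [replace(m, class_label=classify(m, config)) for m in metrics]


@dataclass
class ImageResult:
    """Classified measurements for one image."""

    source: Path
    particles: list[ParticleMetrics] = field(default_factory=list)

    @property
    def pellet_area_total(self) -> float:
        return sum(p.area for p in self.particles if p.class_label == "pellet")

    @property
    def dispersed_area_total(self) -> float:
        return sum(p.area for p in self.particles if p.class_label == "dispersed")


def pellet_fraction(results: Sequence[ImageResult]) -> float:
    """Pelleted percentage of total fungal area, pooled over a directory.

    Areas are pooled before dividing (not averaged per image), so splitting
    a directory's images into halves and pooling reproduces the whole-
    directory value. Zero total fungal area is undefined and returns NaN
    with a warning.
    """
    pellet = sum(r.pellet_area_total for r in results)
    dispersed = sum(r.dispersed_area_total for r in results)
    total = pellet + dispersed
    if total <= 0:
        logger.warning("zero total fungal area: pellet fraction undefined")
        return math.nan
    return 100.0 * pellet / total


def drop_flagged(result: ImageResult, flagged: set[int]) -> ImageResult:
    """Remove particles flagged during visual QC from an image's results.

    The QC overlays let a user spot wrong automated calls; this is the
    re-entry path that removes those calls from every CSV and total.
    """
    known = {p.index for p in result.particles}
    unknown = set(flagged) - known
    if unknown:
        raise ValidationError(
            f"{result.source}: flagged particle indices not present: {sorted(unknown)}"
        )
    if flagged:
        logger.info("%s: removing %d QC-flagged particles", result.source, len(flagged))
    kept = [p for p in result.particles if p.index not in flagged]
    return ImageResult(source=result.source, particles=kept)


def read_qc_flags(path: Path | str) -> dict[str, set[int]]:
    """Read a QC flag CSV (columns: image_path, particle_index)."""
    flags: dict[str, set[int]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"image_path", "particle_index"} <= set(
            reader.fieldnames
        ):
            raise ValidationError(
                f"{path}: QC flag file needs columns image_path, particle_index"
            )
        for rec in reader:
            try:
                idx = int(rec["particle_index"])
            except (TypeError, ValueError):
                raise ValidationError(
                    f"{path}: bad particle_index {rec['particle_index']!r}"
                ) from None
            flags.setdefault(rec["image_path"], set()).add(idx)
    return flags


def _draw_outlines(
    base: Image.Image, items: Sequence[tuple[ParticleMetrics, Particle]]
) -> Image.Image:
    img = base.copy()
    draw = ImageDraw.Draw(img)
    font = ImageFont.load_default()
    for metrics, particle in items:
        pts = [(float(x), float(y)) for x, y in particle.outline]
        draw.polygon(pts, outline=RED, width=1)
        cx, cy = particle.centroid
        draw.text((cx, cy), str(metrics.index), fill=RED, font=font, anchor="mm")
    return img


def render_qc_overlays(
    record: ImageRecord,
    classified: Sequence[tuple[ParticleMetrics, Particle]],
    out_dir: Path | str,
) -> tuple[Path, Path]:
    """Write the two indexed QC overlay PNGs for one raw image.

    One overlay draws only pellet outlines, the other only dispersed
    outlines; each outline is annotated in red with the particle index
    that identifies its row in the raw CSV. Artefacts are never drawn.
    """
    out_dir = Path(out_dir)
    base = Image.fromarray(record.raster)
    stem = record.path.stem
    paths = []
    for cls in ("pellet", "dispersed"):
        items = [(m, p) for m, p in classified if m.class_label == cls]
        overlay = _draw_outlines(base, items)
        path = out_dir / f"{stem}_{cls}_qc.png"
        try:
            path.parent.mkdir(parents=True, exist_ok=True)
            overlay.save(path)
        except OSError as exc:
            raise ImageIOError(f"cannot write overlay {path}: {exc}") from exc
        paths.append(path)
    return paths[0], paths[1]


def linear_fit_r2(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Ordinary least-squares line with its coefficient of determination.

    Returns (slope, intercept, R²) with R² = 1 − SS_res/SS_tot. Intended
    for correlating morphology summaries (mean pellet diameter, MN, …)
    with external scalar measurements. Constant y gives a flat line with
    R² = 0 and a warning; constant x is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValidationError("linear fit needs ≥ 2 paired points")
    if np.ptp(x) == 0:
        raise ValidationError("linear fit undefined for constant x")
    if np.ptp(y) == 0:
        logger.warning("constant y: R² reported as 0")
        return 0.0, float(y[0]), 0.0
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return float(slope), float(intercept), 1.0 - ss_res / ss_tot
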