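"""Euclidian shape descriptors and the dimensionless morphology number.

For each particle four calibrated descriptors are computed:

* **area** (µm²) — foreground pixel count times the squared pixel size;
* **Feret's diameter** (µm) — the maximum caliper diameter of the convex
  hull (the longest span between two parallel supporting lines), with the
  minimum caliper width as its counterpart;
* **aspect ratio** — maximum / minimum Feret diameter, ≥ 1, equal to 1
  for isotropic shapes;
* **solidity** — particle area divided by convex-hull area, 1 for convex
  shapes and decreasing toward 0 with increasing surface irregularity.

These combine into the morphology number

    MN = (2 · √Area · Solidity) / (√π · Feret · AspectRatio)

a dimensionless composite equal to 1 for a perfect circle and tending to
0 for a one-dimensional line, so a single value captures how far a
particle is from an ideal pellet. MN is reported unclamped: rasterization
can push it marginally above 1 and that is left visible.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ContractViolation
from .imaging_io import Calibration
from .segmentation import Particle, polygon_area


@dataclass
class ParticleMetrics:
    """Calibrated descriptors for one particle."""

    index: int
    image: str
    area: float  # µm²
    feret_max: float  # µm
    feret_min: float  # µm
    aspect_ratio: float
    solidity: float
    morphology_number: float
    class_label: str = "unclassified"

    def as_row(self) -> dict:
        return {
            "index": self.index,
            "image": self.image,
            "class": self.class_label,
            "area_um2": self.area,
            "feret_max_um": self.feret_max,
            "feret_min_um": self.feret_min,
            "aspect_ratio": self.aspect_ratio,
            "solidity": self.solidity,
            "morphology_number": self.morphology_number,
        }


def area_um2(particle: Particle, cal: Calibration) -> float:
    """Calibrated particle area: pixel count × (µm/px)²."""
    return particle.pixel_count * cal.area_factor


def _caliper_extremes(hull: np.ndarray) -> tuple[float, float]:
    """Rotating-calipers max diameter and min width of a convex CCW polygon."""
    pts = np.asarray(hull, dtype=float)
    n = len(pts)
    if n < 2:
        raise ContractViolation("degenerate hull: fewer than 2 vertices")
    if n == 2:
        d = float(np.linalg.norm(pts[1] - pts[0]))
        return d, 0.0

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    # max distance over antipodal vertex pairs
    max_d2 = 0.0
    k = 1
    for i in range(n):
        j = (i + 1) % n
        # advance the caliper while the triangle area keeps growing
        while abs(cross(pts[i], pts[j], pts[(k + 1) % n])) > abs(
            cross(pts[i], pts[j], pts[k])
        ):
            k = (k + 1) % n
        for v in (i, j):
            d2 = float(np.sum((pts[k] - pts[v]) ** 2))
            if d2 > max_d2:
                max_d2 = d2

    # min width: smallest over edge orientations of the supporting-line gap
    min_w = math.inf
    for i in range(n):
        j = (i + 1) % n
        edge = pts[j] - pts[i]
        length = float(np.linalg.norm(edge))
        if length == 0:
            continue
        # perpendicular distances of all vertices to the edge line
        d = np.abs((pts[:, 0] - pts[i][0]) * edge[1] - (pts[:, 1] - pts[i][1]) * edge[0]) / length
        min_w = min(min_w, float(d.max()))
    return math.sqrt(max_d2), min_w


def feret_extremes(hull: np.ndarray, cal: Calibration) -> tuple[float, float]:
    """Maximum and minimum Feret (caliper) diameters of a convex hull, in µm.

    The maximum is the largest vertex-pair distance, found with rotating
    calipers over antipodal pairs; the minimum is the smallest projection
    width over hull-edge orientations.
    """
    fmax_px, fmin_px = _caliper_extremes(hull)
    if fmin_px <= 0:
        raise ContractViolation("degenerate hull: zero caliper width")
    return cal.length_um(fmax_px), cal.length_um(fmin_px)


def aspect_ratio(feret_max: float, feret_min: float) -> float:
    """Maximum over minimum Feret diameter; ≥ 1 by construction."""
    if feret_min <= 0:
        raise ContractViolation(f"feret_min must be > 0, got {feret_min}")
    return feret_max / feret_min


def solidity(particle_area: float, hull_area: float) -> float:
    """Observed area over convex-hull area, in (0, 1] for valid particles.

    Hull area comes from the hull polygon (shoelace) and particle area
    from the calibrated pixel count; both in the same units.
    """
    if particle_area <= 0:
        raise ContractViolation(f"particle area must be > 0, got {particle_area}")
    if hull_area < particle_area:
        raise ContractViolation(
            f"hull area {hull_area} smaller than particle area {particle_area}"
        )
    return particle_area / hull_area


def morphology_number(
    area: float, solidity: float, feret_max: float, aspect_ratio: float
) -> float:
    """MN = (2·√Area·Solidity) / (√π·Feret·AspectRatio), dimensionless."""
    if min(area, solidity, feret_max, aspect_ratio) <= 0:
        raise ContractViolation("morphology number requires strictly positive inputs")
    return 2.0 * math.sqrt(area) * solidity / (math.sqrt(math.pi) * feret_max * aspect_ratio)


def compute_metrics(particle: Particle, cal: Calibration, image: str = "") -> ParticleMetrics:
    """All descriptors for one particle, in calibrated physical units."""
    a = area_um2(particle, cal)
    fmax, fmin = feret_extremes(particle.hull, cal)
    ar = aspect_ratio(fmax, fmin)
    # hull polygon area ≥ outline polygon area ≥ pixel count, so sol ≤ 1
    hull_area_um2 = abs(polygon_area(particle.hull)) * cal.area_factor
    sol = solidity(a, hull_area_um2)
    mn = morphology_number(a, sol, fmax, ar)
    return ParticleMetrics(
        index=particle.index,
        image=image or (particle.source.name if particle.source else ""),
        area=a,
        feret_max=fmax,
        feret_min=fmin,
        aspect_ratio=ar,
        solidity=sol,
        morphology_number=mn,
    )
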