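"""Seed-reproducible synthetic culture scenes with analytic ground truth.

Emulates the capture protocol the pipeline targets — bright fungal
structures on a dark background — with parametric shapes whose
descriptors are known in closed form: discs (the ideal pellet, MN = 1),
ellipses and rectangles (dispersed fragments), crosses (concave shapes
with exact solidity), and blob unions of discs whose truth is computed
numerically at 10× supersampling and tagged as derived rather than
analytic. Every rendered shape carries its expected class under a stated
classification config, so whole-pipeline recovery can be asserted
without microscope data.

Rasterization uses a pixel-centre inclusion test against the analytic
shape, which is unbiased and converges to the analytic truth as the
shape grows relative to the pixel size.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

from .errors import ConfigurationError, ImageIOError
from .imaging_io import Calibration, ClassificationConfig, ImageRecord

DEFAULT_FOREGROUND = 200
DEFAULT_BACKGROUND = 20


@dataclass
class ShapeTruth:
    """Ground-truth descriptors of a shape, in physical units."""

    area_um2: float
    feret_max_um: float
    feret_min_um: float
    aspect_ratio: float
    solidity: float
    morphology_number: float
    derived: bool = False  # True when computed numerically, not closed-form

    def expected_class(self, config: ClassificationConfig) -> str:
        if self.area_um2 >= config.pellet_min_area:
            return "pellet"
        if self.area_um2 >= config.dispersed_min_area:
            return "dispersed"
        return "artefact"

    def as_dict(self) -> dict:
        return {
            "area_um2": self.area_um2,
            "feret_max_um": self.feret_max_um,
            "feret_min_um": self.feret_min_um,
            "aspect_ratio": self.aspect_ratio,
            "solidity": self.solidity,
            "morphology_number": self.morphology_number,
            "derived": self.derived,
        }


def _mn(area: float, sol: float, feret: float, ar: float) -> float:
    return 2.0 * math.sqrt(area) * sol / (math.sqrt(math.pi) * feret * ar)


def _poly_feret_bruteforce(vertices: np.ndarray) -> tuple[float, float]:
    """Feret extremes of a convex polygon by exhaustive search (truth oracle)."""
    pts = np.asarray(vertices, dtype=float)
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    fmax = float(d.max())
    n = len(pts)
    fmin = math.inf
    for i in range(n):
        e = pts[(i + 1) % n] - pts[i]
        ln = float(np.hypot(*e))
        if ln == 0:
            continue
        dist = np.abs((pts[:, 0] - pts[i, 0]) * e[1] - (pts[:, 1] - pts[i, 1]) * e[0]) / ln
        fmin = min(fmin, float(dist.max()))
    return fmax, fmin


def _shoelace(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y)))


@dataclass
class SyntheticShapeSpec:
    """A parametric shape (dimensions in µm) with computable ground truth."""

    kind: str  # disc | ellipse | rectangle | cross | blob
    params: dict
    centre: tuple[float, float]  # (x, y) in µm
    rotation: float = 0.0  # degrees
    intensity: int = DEFAULT_FOREGROUND

    def __post_init__(self) -> None:
        if self.kind not in ("disc", "ellipse", "rectangle", "cross", "blob"):
            raise ConfigurationError(f"unknown shape kind {self.kind!r}")
        if not (0 <= self.intensity <= 255):
            raise ConfigurationError(f"intensity out of 8-bit range: {self.intensity}")

    # -- geometry ---------------------------------------------------------

    @property
    def half_extent(self) -> float:
        """Radius of a circle guaranteed to contain the shape, µm."""
        p = self.params
        if self.kind == "disc":
            return p["radius"]
        if self.kind == "ellipse":
            return max(p["a"], p["b"])
        if self.kind == "rectangle":
            return math.hypot(p["width"], p["height"]) / 2
        if self.kind == "cross":
            return math.hypot(p["length"], p["thickness"]) / 2
        return max(math.hypot(dx, dy) + r for dx, dy, r in p["discs"])

    def _to_local(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        dx, dy = x - self.centre[0], y - self.centre[1]
        th = math.radians(self.rotation)
        c, s = math.cos(th), math.sin(th)
        return c * dx + s * dy, -s * dx + c * dy

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Inclusion test for points given in µm scene coordinates."""
        u, v = self._to_local(np.asarray(x, float), np.asarray(y, float))
        p = self.params
        if self.kind == "disc":
            return u * u + v * v <= p["radius"] ** 2
        if self.kind == "ellipse":
            return (u / p["a"]) ** 2 + (v / p["b"]) ** 2 <= 1.0
        if self.kind == "rectangle":
            return (np.abs(u) <= p["width"] / 2) & (np.abs(v) <= p["height"] / 2)
        if self.kind == "cross":
            half_l, half_t = p["length"] / 2, p["thickness"] / 2
            bar1 = (np.abs(u) <= half_l) & (np.abs(v) <= half_t)
            bar2 = (np.abs(u) <= half_t) & (np.abs(v) <= half_l)
            return bar1 | bar2
        inside = np.zeros(np.shape(u), dtype=bool)
        for dx, dy, r in p["discs"]:
            inside |= (u - dx) ** 2 + (v - dy) ** 2 <= r * r
        return inside

    # -- ground truth -----------------------------------------------------

    def truth(self, supersample: int = 10) -> ShapeTruth:
        """Descriptor ground truth; closed-form except for blobs."""
        p = self.params
        if self.kind == "disc":
            r = p["radius"]
            return ShapeTruth(math.pi * r * r, 2 * r, 2 * r, 1.0, 1.0, 1.0)
        if self.kind == "ellipse":
            a, b = p["a"], p["b"]
            if a < b:
                a, b = b, a
            area = math.pi * a * b
            return ShapeTruth(area, 2 * a, 2 * b, a / b, 1.0, (b / a) ** 1.5)
        if self.kind == "rectangle":
            w, h = p["width"], p["height"]
            area = w * h
            fmax = math.hypot(w, h)
            fmin = min(w, h)
            ar = fmax / fmin
            return ShapeTruth(area, fmax, fmin, ar, 1.0, _mn(area, 1.0, fmax, ar))
        if self.kind == "cross":
            L, t = p["length"], p["thickness"]
            area = 2 * L * t - t * t
            hull_area = L * L - (L - t) ** 2 / 2
            sol = area / hull_area
            hl, ht = L / 2, t / 2
            octagon = np.array(
                [(-ht, -hl), (ht, -hl), (hl, -ht), (hl, ht),
                 (ht, hl), (-ht, hl), (-hl, ht), (-hl, -ht)]
            )
            fmax, fmin = _poly_feret_bruteforce(octagon)
            ar = fmax / fmin
            return ShapeTruth(area, fmax, fmin, ar, sol, _mn(area, sol, fmax, ar))
        # blob: numeric truth at `supersample`× the µm grid
        ext = self.half_extent * 1.05
        step = 1.0 / supersample
        g = np.arange(-ext, ext + step, step)
        u, v = np.meshgrid(g, g)
        inside = np.zeros(u.shape, dtype=bool)
        for dx, dy, r in p["discs"]:
            inside |= (u - dx) ** 2 + (v - dy) ** 2 <= r * r
        area = float(inside.sum()) * step * step
        ring = []
        for dx, dy, r in p["discs"]:
            th = np.linspace(0, 2 * math.pi, 720, endpoint=False)
            ring.append(np.column_stack([dx + r * np.cos(th), dy + r * np.sin(th)]))
        pts = np.vstack(ring)
        from scipy.spatial import ConvexHull

        hull = pts[ConvexHull(pts).vertices]
        hull_area = _shoelace(hull)
        sol = min(1.0, area / hull_area)
        fmax, fmin = _poly_feret_bruteforce(hull)
        ar = fmax / fmin
        return ShapeTruth(area, fmax, fmin, ar, sol, _mn(area, sol, fmax, ar), derived=True)


@dataclass
class SceneSpec:
    """One synthetic image: canvas, calibration, noise, and its shapes."""

    canvas_px: tuple[int, int]  # (height, width)
    calibration: Calibration
    shapes: list[SyntheticShapeSpec] = field(default_factory=list)
    background: int = DEFAULT_BACKGROUND
    noise_sigma: float = 0.0
    allow_border_overlap: bool = False
    allow_overlap: bool = False
    seed: int = 0


def make_shape(
    spec: SyntheticShapeSpec, cal: Calibration, canvas_px: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize one shape by pixel-centre inclusion: (rows, cols) arrays."""
    h, w = canvas_px
    upp = cal.um_per_px
    ext_px = spec.half_extent / upp + 1
    cx_px, cy_px = spec.centre[0] / upp, spec.centre[1] / upp
    r_lo = max(0, int(math.floor(cy_px - ext_px)))
    r_hi = min(h, int(math.ceil(cy_px + ext_px)) + 1)
    c_lo = max(0, int(math.floor(cx_px - ext_px)))
    c_hi = min(w, int(math.ceil(cx_px + ext_px)) + 1)
    if r_lo >= r_hi or c_lo >= c_hi:
        return np.array([], dtype=int), np.array([], dtype=int)
    rr, cc = np.meshgrid(np.arange(r_lo, r_hi), np.arange(c_lo, c_hi), indexing="ij")
    x_um = (cc + 0.5) * upp
    y_um = (rr + 0.5) * upp
    inside = spec.contains(x_um, y_um)
    return rr[inside], cc[inside]


def render_scene(
    spec: SceneSpec, path: Path | str = "synthetic_scene.png"
) -> tuple[ImageRecord, list[dict]]:
    """Render an RGB scene (light shapes on dark) plus its truth manifest.

    Identical spec and seed give byte-identical pixels. Shapes crossing
    the canvas border, or overlapping each other, are errors unless the
    spec explicitly allows them.
    """
    h, w = spec.canvas_px
    grey = np.full((h, w), spec.background, dtype=np.float64)
    occupied = np.zeros((h, w), dtype=bool)
    manifest: list[dict] = []
    config = ClassificationConfig()
    for i, shape in enumerate(spec.shapes):
        rr, cc = make_shape(shape, spec.calibration, spec.canvas_px)
        if rr.size == 0:
            raise ConfigurationError(f"shape {i} ({shape.kind}) rasterizes to nothing")
        touches = rr.min() == 0 or cc.min() == 0 or rr.max() == h - 1 or cc.max() == w - 1
        clipped = (
            shape.centre[0] - shape.half_extent < 0
            or shape.centre[1] - shape.half_extent < 0
            or shape.centre[0] + shape.half_extent > w * spec.calibration.um_per_px
            or shape.centre[1] + shape.half_extent > h * spec.calibration.um_per_px
        )
        if (touches or clipped) and not spec.allow_border_overlap:
            raise ConfigurationError(f"shape {i} ({shape.kind}) crosses the canvas border")
        if occupied[rr, cc].any() and not spec.allow_overlap:
            raise ConfigurationError(f"shape {i} ({shape.kind}) overlaps another shape")
        occupied[rr, cc] = True
        grey[rr, cc] = shape.intensity
        truth = shape.truth()
        manifest.append(
            {
                "shape": shape.kind,
                "centre_um": list(shape.centre),
                "rotation_deg": shape.rotation,
                "touches_border": bool(touches or clipped),
                "pixel_count": int(rr.size),
                **truth.as_dict(),
                "expected_class": truth.expected_class(config),
            }
        )
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        grey = grey + rng.normal(0.0, spec.noise_sigma, size=grey.shape)
    raster = np.clip(np.rint(grey), 0, 255).astype(np.uint8)
    rgb = np.stack([raster] * 3, axis=-1)
    return ImageRecord(path=Path(path), subdir=".", raster=rgb), manifest


def standard_scene(
    seed: int = 0,
    noise_sigma: float = 0.0,
    include_border_disc: bool = True,
    um_per_px: float = 1.0,
) -> SceneSpec:
    """The reference test scene: 3 pellet discs, 5 dispersed rectangles,
    2 sub-artefact specks, and (optionally) one disc straddling the border.

    All dimensions in µm on a 512×512 px canvas. Under the default
    classification config the interior shapes are 3 pellets (discs of
    radius 20/16/24 µm), 5 dispersed fragments (rectangles of 95–500 µm²)
    and 2 artefacts (discs of radius 3 and 4 µm).
    """
    shapes = [
        SyntheticShapeSpec("disc", {"radius": 20.0}, (80.0, 80.0)),
        SyntheticShapeSpec("disc", {"radius": 16.0}, (240.0, 90.0)),
        SyntheticShapeSpec("disc", {"radius": 24.0}, (400.0, 100.0)),
        SyntheticShapeSpec("rectangle", {"width": 20.0, "height": 10.0}, (80.0, 220.0), 15.0),
        SyntheticShapeSpec("rectangle", {"width": 15.0, "height": 12.0}, (200.0, 230.0), 40.0),
        SyntheticShapeSpec("rectangle", {"width": 25.0, "height": 8.0}, (320.0, 220.0), 75.0),
        SyntheticShapeSpec("rectangle", {"width": 14.0, "height": 10.0}, (430.0, 230.0), 0.0),
        SyntheticShapeSpec("rectangle", {"width": 11.0, "height": 11.0}, (100.0, 360.0), 30.0),
        SyntheticShapeSpec("disc", {"radius": 3.0}, (220.0, 370.0)),
        SyntheticShapeSpec("disc", {"radius": 4.0}, (330.0, 360.0)),
    ]
    if include_border_disc:
        shapes.append(SyntheticShapeSpec("disc", {"radius": 18.0}, (512.0, 450.0)))
    return SceneSpec(
        canvas_px=(512, 512),
        calibration=Calibration(um_per_px),
        shapes=shapes,
        noise_sigma=noise_sigma,
        allow_border_overlap=include_border_disc,
        seed=seed,
    )


def _random_scene(
    rng: np.random.Generator,
    composition: dict[str, int],
    canvas_px: tuple[int, int],
    cal: Calibration,
    noise_sigma: float,
) -> SceneSpec:
    """Place shapes of requested classes on a jittered grid (no overlaps)."""
    h, w = canvas_px
    upp = cal.um_per_px
    cell = 128
    n_rows, n_cols = h // cell, w // cell
    cells = [(r, c) for r in range(n_rows) for c in range(n_cols)]
    total = sum(composition.values())
    if total > len(cells):
        raise ConfigurationError(
            f"{total} shapes do not fit a {n_rows}×{n_cols} placement grid"
        )
    picks = rng.permutation(len(cells))[:total]
    shapes = []
    kinds = (
        ["pellet"] * composition.get("pellet", 0)
        + ["dispersed"] * composition.get("dispersed", 0)
        + ["artefact"] * composition.get("artefact", 0)
    )
    for kind, ci in zip(kinds, picks):
        r, c = cells[ci]
        jitter = rng.uniform(-10, 10, size=2)
        cx = (c * cell + cell / 2 + jitter[0]) * upp
        cy = (r * cell + cell / 2 + jitter[1]) * upp
        if kind == "pellet":
            radius = float(rng.uniform(14.0, 30.0))
            shapes.append(SyntheticShapeSpec("disc", {"radius": radius}, (cx, cy)))
        elif kind == "dispersed":
            width = float(rng.uniform(12.0, 24.0))
            height = float(rng.uniform(8.0, 16.0))
            rot = float(rng.uniform(0, 90))
            shapes.append(
                SyntheticShapeSpec(
                    "rectangle", {"width": width, "height": height}, (cx, cy), rot
                )
            )
        else:
            radius = float(rng.uniform(2.0, 5.0))
            shapes.append(SyntheticShapeSpec("disc", {"radius": radius}, (cx, cy)))
    return SceneSpec(
        canvas_px=canvas_px,
        calibration=cal,
        shapes=shapes,
        noise_sigma=noise_sigma,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def make_test_tree(
    root: Path | str,
    n_subdirs: int = 2,
    images_per_subdir: int = 3,
    composition: dict[str, int] | None = None,
    seed: int = 0,
    canvas_px: tuple[int, int] = (512, 512),
    um_per_px: float = 1.0,
    noise_sigma: float = 0.0,
) -> dict:
    """Write a nested tree of synthetic PNGs plus a JSON truth manifest.

    Layout: ``root/s01/img_001.png …`` with one sub-directory per
    simulated culture condition. The manifest records every shape's truth
    and the analytic pellet fraction expected per sub-directory.
    """
    if n_subdirs < 1 or images_per_subdir < 1:
        raise ConfigurationError("need at least one sub-directory and one image each")
    composition = composition or {"pellet": 3, "dispersed": 4, "artefact": 1}
    root = Path(root)
    try:
        root.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise ImageIOError(f"cannot create fixture root {root}: {exc}") from exc
    rng = np.random.default_rng(seed)
    cal = Calibration(um_per_px)
    manifest: dict = {"seed": seed, "um_per_px": um_per_px, "subdirs": {}}
    for si in range(1, n_subdirs + 1):
        sub = f"s{si:02d}"
        subdir = root / sub
        subdir.mkdir(exist_ok=True)
        pellet_area = dispersed_area = 0.0
        images = {}
        for ii in range(1, images_per_subdir + 1):
            name = f"img_{ii:03d}.png"
            scene = _random_scene(rng, composition, canvas_px, cal, noise_sigma)
            record, shapes = render_scene(scene, subdir / name)
            Image.fromarray(record.raster).save(subdir / name)
            for s in shapes:
                if s["expected_class"] == "pellet":
                    pellet_area += s["area_um2"]
                elif s["expected_class"] == "dispersed":
                    dispersed_area += s["area_um2"]
            images[name] = shapes
        total = pellet_area + dispersed_area
        manifest["subdirs"][sub] = {
            "images": images,
            "expected_pellet_fraction_pct": 100.0 * pellet_area / total if total else None,
        }
    with open(root / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
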