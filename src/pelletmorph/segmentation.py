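"""Particle extraction: connected components, outlines, convex hulls.

A particle is a maximal connected set of foreground pixels. Its outline
is a closed polygon of pixel-corner vertices traced along pixel edges
(half-open grid convention: one pixel is a unit square of polygon area 1),
so that for hole-free particles the outline area equals the pixel count
exactly. Interior holes are not filled; particle area always counts
foreground pixels only.

Particle indices are assigned 1..N in raster-scan order of each
component's first pixel and are stable across reruns, which is what ties
a quality-control overlay label to its CSV row.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

from .errors import ContractViolation
from .preprocess import BinaryMask

_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


@dataclass
class Particle:
    """One connected foreground component of a binary mask."""

    index: int
    rows: np.ndarray
    cols: np.ndarray
    outline: np.ndarray  # (N, 2) pixel-corner vertices as (x=col, y=row)
    hull: np.ndarray  # (M, 2) convex polygon, vertices subset of outline
    touches_border: bool
    source: Path | None = None

    @property
    def pixel_count(self) -> int:
        return int(self.rows.size)

    @property
    def centroid(self) -> tuple[float, float]:
        """(x, y) centroid of the pixel centres."""
        return (float(self.cols.mean()) + 0.5, float(self.rows.mean()) + 0.5)


def polygon_area(vertices: np.ndarray) -> float:
    """Signed shoelace area of a closed polygon (positive = CCW)."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def _boundary_edges(sub: np.ndarray, r0: int, c0: int) -> dict[tuple[int, int], list[tuple[int, int]]]:
    """Directed pixel-edge segments of the region boundary, keyed by start vertex.

    Edge directions are chosen so that the region interior lies consistently
    to one side; the resulting outer loop has positive shoelace area.
    """
    pad = np.pad(sub, 1)
    core = pad[1:-1, 1:-1]
    open_top = core & ~pad[:-2, 1:-1]
    open_bottom = core & ~pad[2:, 1:-1]
    open_left = core & ~pad[1:-1, :-2]
    open_right = core & ~pad[1:-1, 2:]

    edges: dict[tuple[int, int], list[tuple[int, int]]] = {}

    def add(rr: np.ndarray, cc: np.ndarray, s_off: tuple[int, int], e_off: tuple[int, int]) -> None:
        for r, c in zip(rr + r0, cc + c0):
            start = (int(c) + s_off[0], int(r) + s_off[1])
            end = (int(c) + e_off[0], int(r) + e_off[1])
            edges.setdefault(start, []).append(end)

    rr, cc = np.nonzero(open_top)
    add(rr, cc, (0, 0), (1, 0))
    rr, cc = np.nonzero(open_right)
    add(rr, cc, (1, 0), (1, 1))
    rr, cc = np.nonzero(open_bottom)
    add(rr, cc, (1, 1), (0, 1))
    rr, cc = np.nonzero(open_left)
    add(rr, cc, (0, 1), (0, 0))
    return edges


def _compress_collinear(loop: list[tuple[int, int]]) -> np.ndarray:
    """Drop vertices interior to straight runs of unit edges."""
    out = []
    n = len(loop)
    for i in range(n):
        p_prev, p, p_next = loop[i - 1], loop[i], loop[(i + 1) % n]
        d1 = (p[0] - p_prev[0], p[1] - p_prev[1])
        d2 = (p_next[0] - p[0], p_next[1] - p[1])
        if d1[0] * d2[1] - d1[1] * d2[0] != 0:
            out.append(p)
    return np.array(out, dtype=float)


def trace_outline(
    pixels: tuple[np.ndarray, np.ndarray] | Iterable[tuple[int, int]],
    connectivity: int = 8,
) -> np.ndarray:
    """Trace the outer boundary of one connected pixel set.

    Returns a closed polygon of pixel-corner vertices, collinear runs
    compressed, oriented with positive shoelace area. At checkerboard
    corners (two diagonal foreground pixels meeting at one vertex) the
    trace passes through under 8-connectivity and turns tightly under
    4-connectivity, matching how the component was labelled.

    Raises :class:`ContractViolation` if the pixels are not one connected
    component under the given connectivity.
    """
    if isinstance(pixels, tuple) and len(pixels) == 2 and isinstance(pixels[0], np.ndarray):
        rows, cols = np.asarray(pixels[0]), np.asarray(pixels[1])
    else:
        pts = np.array(sorted(set((int(r), int(c)) for r, c in pixels)), dtype=int)
        if pts.size == 0:
            raise ContractViolation("empty pixel set")
        rows, cols = pts[:, 0], pts[:, 1]
    r0, c0 = int(rows.min()), int(cols.min())
    sub = np.zeros((int(rows.max()) - r0 + 1, int(cols.max()) - c0 + 1), dtype=bool)
    sub[rows - r0, cols - c0] = True

    _, n_comp = ndimage.label(sub, structure=_STRUCTURES[connectivity])
    if n_comp != 1:
        raise ContractViolation(
            f"pixel set is not a single {connectivity}-connected component ({n_comp} found)"
        )

    edges = _boundary_edges(sub, r0, c0)
    loops: list[list[tuple[int, int]]] = []
    remaining = sum(len(v) for v in edges.values())
    while remaining:
        start = min(v for v, ends in edges.items() if ends)
        loop = [start]
        prev_dir = None
        current = start
        while True:
            ends = edges[current]
            if len(ends) == 1 or prev_dir is None:
                nxt = ends.pop()
            else:
                # pinch vertex: pass through (8-conn) or turn tightly (4-conn)
                crosses = [
                    prev_dir[0] * (e[1] - current[1]) - prev_dir[1] * (e[0] - current[0])
                    for e in ends
                ]
                pick = int(np.argmin(crosses)) if connectivity == 8 else int(np.argmax(crosses))
                nxt = ends.pop(pick)
            remaining -= 1
            prev_dir = (nxt[0] - current[0], nxt[1] - current[1])
            current = nxt
            if current == start:
                break
            loop.append(current)
        loops.append(loop)

    outer = max(loops, key=lambda lp: abs(polygon_area(np.array(lp, dtype=float))))
    poly = _compress_collinear(outer)
    if polygon_area(poly) < 0:
        poly = poly[::-1]
    return poly


def convex_hull(outline: np.ndarray) -> np.ndarray:
    """Minimal convex polygon containing the outline vertices (CCW).

    Hull vertices are a subset of the input vertices. Degenerate inputs
    (fewer than 3 distinct points, or all collinear) cannot arise from
    pixel-corner outlines and raise :class:`ContractViolation`.
    """
    pts = np.asarray(outline, dtype=float)
    try:
        hull = ConvexHull(pts)
    except (QhullError, ValueError) as exc:
        raise ContractViolation(f"degenerate outline for convex hull: {exc}") from exc
    return pts[hull.vertices]


def label_particles(
    mask: BinaryMask | np.ndarray,
    connectivity: int = 8,
    source: Path | None = None,
) -> list[Particle]:
    """Extract maximal connected foreground components as particles.

    Indices run 1..N in raster-scan order of each component's first pixel.
    An empty mask yields an empty list.
    """
    values = mask.values if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)
    if source is None and isinstance(mask, BinaryMask):
        source = mask.provenance
    if connectivity not in _STRUCTURES:
        raise ContractViolation(f"connectivity must be 4 or 8, got {connectivity}")
    labels, n = ndimage.label(values, structure=_STRUCTURES[connectivity])
    if n == 0:
        return []
    # order labels by first pixel in raster-scan order
    flat = labels.ravel()
    uniq, first = np.unique(flat, return_index=True)
    order = sorted((f, u) for u, f in zip(uniq, first) if u != 0)
    objects = ndimage.find_objects(labels)
    h, w = values.shape
    particles: list[Particle] = []
    for rank, (_, lab) in enumerate(order, start=1):
        sl = objects[lab - 1]
        region = labels[sl] == lab
        rr, cc = np.nonzero(region)
        rr = rr + sl[0].start
        cc = cc + sl[1].start
        outline = trace_outline((rr, cc), connectivity=connectivity)
        hull = convex_hull(outline)
        touches = bool(
            rr.min() == 0 or cc.min() == 0 or rr.max() == h - 1 or cc.max() == w - 1
        )
        particles.append(
            Particle(
                index=rank,
                rows=rr,
                cols=cc,
                outline=outline,
                hull=hull,
                touches_border=touches,
                source=source,
            )
        )
    return particles


def apply_border_policy(
    particles: Sequence[Particle],
    mask_shape: tuple[int, int],
    policy: str = "exclude_all",
) -> list[Particle]:
    """Drop border-touching particles (``exclude_all``) or keep everything.

    A particle partially captured at the image edge has truncated, hence
    meaningless, geometry. Surviving particles keep their original indices
    and geometry untouched.
    """
    if policy == "keep_all":
        return list(particles)
    if policy != "exclude_all":
        raise ContractViolation(f"unknown border policy {policy!r}")
    return [p for p in particles if not p.touches_border]
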