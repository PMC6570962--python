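"""Shared fixtures and independent oracles for the test suite.

Oracles here are deliberately naive (BFS flood fill, exhaustive pairwise
searches, shoelace on explicit vertex lists) so they stay independent of
the implementation paths they check.
"""
from __future__ import annotations

from collections import deque

import numpy as np
import pytest

from pelletmorph.imaging_io import Calibration


@pytest.fixture
def cal1() -> Calibration:
    return Calibration(1.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)


def flood_fill_label(mask: np.ndarray, connectivity: int) -> list[set[tuple[int, int]]]:
    """Naive BFS connected components, in raster-scan order of first pixel."""
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    seen = np.zeros_like(mask, dtype=bool)
    comps: list[set[tuple[int, int]]] = []
    h, w = mask.shape
    for r in range(h):
        for c in range(w):
            if mask[r, c] and not seen[r, c]:
                comp = set()
                queue = deque([(r, c)])
                seen[r, c] = True
                while queue:
                    rr, cc = queue.popleft()
                    comp.add((rr, cc))
                    for dr, dc in nbrs:
                        nr, nc = rr + dr, cc + dc
                        if 0 <= nr < h and 0 <= nc < w and mask[nr, nc] and not seen[nr, nc]:
                            seen[nr, nc] = True
                            queue.append((nr, nc))
                comps.append(comp)
    return comps


def brute_force_max_distance(points: np.ndarray) -> float:
    """Max pairwise Euclidean distance by exhaustive search."""
    pts = np.asarray(points, dtype=float)
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def shoelace(vertices) -> float:
    """Unsigned polygon area from an explicit vertex list."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y)))


def disc_mask(radius_px: float, pad: int = 10) -> np.ndarray:
    """Boolean raster of a disc via pixel-centre inclusion, centred mid-canvas."""
    n = int(2 * radius_px) + 2 * pad
    yy, xx = np.mgrid[0:n, 0:n]
    c = n / 2 - 0.5
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius_px**2
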