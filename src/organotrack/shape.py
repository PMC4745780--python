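"""Cohort branching by convex hull and convexity defects.

A CAF cohort's branches make its outline non-convex: between the contour and
its convex hull lie "defect" regions. For each hull gap (the contour run
between two consecutive hull vertices) the farthest contour point from the
hull chord is found; its distance to the chord is the defect depth and
proxies the extension (branch) size. Defects deeper than a threshold count
as reliable extensions.

Contours are (N, 2) arrays of (y, x) vertices ordered along the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull as _SciHull
from scipy.spatial import QhullError

from .fibro import extract_cohorts
from .io import MaskSequence

__all__ = [
    "ConvexityDefect",
    "BranchMetrics",
    "convex_hull",
    "convexity_defects",
    "branch_metrics",
    "branching_series",
]

_EPS = 1e-7


@dataclass
class ConvexityDefect:
    """One contour excursion away from the hull.

    ``start_vertex``/``end_vertex`` are contour indices where the defect
    leaves and rejoins the hull; ``farthest_point`` is the contour index of
    the deepest point; ``depth`` its Euclidean distance to the hull chord.
    """

    start_vertex: int
    end_vertex: int
    farthest_point: int
    depth: float


@dataclass
class BranchMetrics:
    n_extensions: int
    extension_sizes: list[float]
    mean_extension_size: float


def convex_hull(contour: np.ndarray) -> np.ndarray:
    """Indices of the convex hull vertices of a closed contour.

    Returned indices are ordered counter-clockwise in the (x, y) plane and
    every contour point lies inside or on the hull. Raises ValueError for
    fewer than 3 points or collinear input.
    """
    pts = np.asarray(contour, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("contour must be an (N, 2) array with N >= 3")
    try:
        hull = _SciHull(pts[:, ::-1])  # qhull in (x, y); vertices come back CCW
    except QhullError as exc:
        raise ValueError("degenerate (collinear) contour has no 2-D hull") from exc
    return hull.vertices.copy()


def _chord_distance(points: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Euclidean distance of each point to the infinite line through p1, p2."""
    d = p2 - p1
    norm = np.hypot(d[0], d[1])
    if norm < _EPS:
        return np.hypot(points[:, 0] - p1[0], points[:, 1] - p1[1])
    cross = (points[:, 0] - p1[0]) * d[1] - (points[:, 1] - p1[1]) * d[0]
    return np.abs(cross) / norm


def convexity_defects(contour: np.ndarray,
                      hull_indices: np.ndarray) -> list[ConvexityDefect]:
    """One defect per hull gap that contains contour points off the chord.

    For consecutive hull vertices (in contour order) the intermediate contour
    run is examined; the deepest point and its point-to-chord distance define
    the defect. Gaps whose intermediate points all lie on the chord (a convex
    contour) yield no defect.
    """
    pts = np.asarray(contour, dtype=float)
    n = len(pts)
    hull_sorted = np.sort(np.asarray(hull_indices))
    defects: list[ConvexityDefect] = []
    for a, b in zip(hull_sorted, np.roll(hull_sorted, -1)):
        if b > a:
            run = np.arange(a + 1, b)
        else:  # wrap around the closed contour
            run = np.concatenate([np.arange(a + 1, n), np.arange(0, b)])
        if run.size == 0:
            continue
        dist = _chord_distance(pts[run], pts[a], pts[b])
        k = int(np.argmax(dist))
        if dist[k] <= _EPS:
            continue
        defects.append(ConvexityDefect(int(a), int(b), int(run[k]),
                                       float(dist[k])))
    return defects


def branch_metrics(contour: np.ndarray,
                   depth_threshold: float = 5.0) -> BranchMetrics:
    """Extensions of one cohort: defects with depth > ``depth_threshold``.

    Zero surviving defects give mean_extension_size = 0.
    """
    hull = convex_hull(contour)
    defects = convexity_defects(contour, hull)
    sizes = [d.depth for d in defects if d.depth > depth_threshold]
    mean = float(np.mean(sizes)) if sizes else 0.0
    return BranchMetrics(len(sizes), sizes, mean)


def branching_series(masks: MaskSequence, depth_threshold: float = 5.0,
                     min_area: int = 50) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame mean extension count and mean extension size across cohorts.

    Cohorts below ``min_area`` are excluded; frames with no cohorts yield
    NaN in both outputs.
    """
    n = masks.n_frames
    counts = np.full(n, np.nan)
    sizes = np.full(n, np.nan)
    for t, mask in enumerate(masks.frames):
        regions = [r for r in extract_cohorts(mask) if r.area >= min_area]
        if not regions:
            continue
        per_counts, per_sizes = [], []
        for reg in regions:
            bm = branch_metrics(reg.contour, depth_threshold)
            per_counts.append(bm.n_extensions)
            per_sizes.append(bm.mean_extension_size)
        counts[t] = float(np.mean(per_counts))
        sizes[t] = float(np.mean(per_sizes))
    return counts, sizes
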