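"""Polygon and polyline primitives shared by the pipeline stages.

Contours are (N, 2) float arrays of ``(x, y)`` vertices describing a closed
ring; the closing edge from the last vertex back to the first is implicit
(vertices are stored "open").
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import Polygon

from leafmorph.errors import GeometryError

__all__ = [
    "as_contour",
    "signed_area",
    "perimeter",
    "is_simple",
    "ensure_orientation",
    "canonical_start",
    "fill_polygon",
    "points_to_polyline_distance",
]


def as_contour(points) -> np.ndarray:
    """Validate and return a contour as an open (N, 2) float ring."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise GeometryError(f"contour must be (N, 2), got {pts.shape}")
    if len(pts) > 1 and np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    if len(pts) < 3:
        raise GeometryError("contour needs at least 3 distinct vertices")
    return pts


def signed_area(points: np.ndarray) -> float:
    """Shoelace signed area (standard formula); negative for a contour
    traversed counter-clockwise as displayed in y-down image coordinates."""
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def perimeter(points: np.ndarray) -> float:
    d = np.diff(np.vstack([points, points[:1]]), axis=0)
    return float(np.sum(np.hypot(d[:, 0], d[:, 1])))


def is_simple(points: np.ndarray) -> bool:
    poly = Polygon(points)
    return poly.is_valid and poly.is_simple and poly.area > 0


def ensure_orientation(points: np.ndarray, positive: bool = True) -> np.ndarray:
    """Flip traversal direction so the shoelace sign matches ``positive``."""
    a = signed_area(points)
    if a == 0:
        raise GeometryError("zero-area contour has no orientation")
    if (a > 0) != positive:
        return points[::-1].copy()
    return points


def canonical_start(points: np.ndarray) -> np.ndarray:
    """Rotate the vertex list so it starts at the lexicographically
    smallest (y, x) vertex — a deterministic anchor for testing."""
    idx = np.lexsort((points[:, 0], points[:, 1]))[0]
    return np.roll(points, -idx, axis=0)


def fill_polygon(points: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a polygon to a boolean mask (pixel-center even-odd rule).

    A pixel (row r, col c) is foreground when its center (c, r) lies inside
    the polygon. Scanline toggling makes this O(V + H*W) independent of the
    vertex count, unlike generic point-in-polygon rasterizers.
    """
    H, W = shape
    pts = np.asarray(points, dtype=float)
    x1, y1 = pts[:, 0], pts[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)

    # half-open rule: an edge crosses scanline y=r iff min(y) <= r < max(y)
    ylo = np.minimum(y1, y2)
    yhi = np.maximum(y1, y2)
    r_start = np.ceil(ylo).astype(int)
    r_stop = np.ceil(yhi).astype(int)  # exclusive
    counts = np.clip(r_stop, 0, H) - np.clip(r_start, 0, H)
    counts = np.maximum(counts, 0)
    keep = counts > 0
    if not keep.any():
        return np.zeros(shape, dtype=bool)
    idx = np.repeat(np.nonzero(keep)[0], counts[keep])
    offs = np.concatenate([np.arange(c) for c in counts[keep]])
    rows = np.clip(r_start[idx], 0, H) + offs
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (rows - y1[idx]) / (y2[idx] - y1[idx])
    xs = x1[idx] + t * (x2[idx] - x1[idx])

    toggles = np.zeros((H, W + 1), dtype=np.int64)
    cols = np.clip(np.ceil(xs).astype(int), 0, W)
    np.add.at(toggles, (rows, cols), 1)
    inside = np.cumsum(toggles[:, :-1], axis=1) % 2 == 1
    return inside


def points_to_polyline_distance(
    points: np.ndarray, ring: np.ndarray, chunk: int = 512
) -> np.ndarray:
    """Euclidean distance from each query point to the closed polyline.

    Distances are point-to-nearest-point-on-segment over every edge of the
    ring (including the closing edge), vectorized in chunks to bound memory.
    """
    pts = np.asarray(points, dtype=float)
    ring = np.asarray(ring, dtype=float)
    seg_a = ring
    seg_b = np.roll(ring, -1, axis=0)
    d = seg_b - seg_a  # (M, 2)
    len2 = np.einsum("ij,ij->i", d, d)
    len2 = np.where(len2 == 0.0, 1.0, len2)

    out = np.empty(len(pts))
    for lo in range(0, len(pts), chunk):
        p = pts[lo : lo + chunk]  # (m, 2)
        # projection parameter of each point on each segment, clamped
        w = p[:, None, :] - seg_a[None, :, :]  # (m, M, 2)
        t = np.clip(np.einsum("pmi,mi->pm", w, d) / len2, 0.0, 1.0)
        closest = seg_a[None, :, :] + t[:, :, None] * d[None, :, :]
        diff = p[:, None, :] - closest
        dist2 = np.einsum("pmi,pmi->pm", diff, diff)
        out[lo : lo + chunk] = np.sqrt(dist2.min(axis=1))
    return out
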