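"""Shape-difference and axial-symmetry metrics on normalized contours.

All distances are in the normalized plane whose unit is the "image point"
of the 1000-point first-harmonic major diameter.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from leafmorph.efd import MAJOR_DIAMETER, EFDCoefficients, NormalizedShape
from leafmorph.errors import (
    ConfigurationError,
    DegeneratePopulationError,
    ResolutionError,
)
from leafmorph.geometry import fill_polygon, points_to_polyline_distance

__all__ = [
    "PairComparison",
    "SymmetryResult",
    "relative_area_difference",
    "contour_distances",
    "efd_distance",
    "mirror_shape",
    "symmetry_error_distance",
    "symmetry_error_area",
    "compare_pair",
    "population_ratios",
    "DEFAULT_BIN_WIDTH",
    "DEFAULT_GRID_RESOLUTION",
]

DEFAULT_BIN_WIDTH = 10.0
DEFAULT_GRID_RESOLUTION = 2048
MIN_GRID_ACROSS_AXIS = 256


@dataclass
class PairComparison:
    """Metric bundle for one leaf pair."""

    id1: str
    id2: str
    category: str  # e.g. "cc" (control-control) or "ct" (control-touched)
    delta_area: float
    d_avg: float
    d_max: float
    D2: float
    histogram: np.ndarray | None = None
    bin_width: float = DEFAULT_BIN_WIDTH


@dataclass
class SymmetryResult:
    """Axial-symmetry errors of one leaf."""

    id: str
    e_d: float
    epsilon_a: float


def relative_area_difference(area1: float, area2: float) -> float:
    """2|A1 - A2| / (A1 + A2): relative area difference of a leaf pair."""
    if area1 <= 0 or area2 <= 0:
        raise ConfigurationError(f"areas must be > 0, got ({area1}, {area2})")
    return 2.0 * abs(area1 - area2) / (area1 + area2)


def _directed_distances(pts: np.ndarray, other: np.ndarray, indexed: bool) -> np.ndarray:
    if indexed:
        return np.hypot(*(pts - other).T)
    return points_to_polyline_distance(pts, other)


def contour_distances(
    s1: NormalizedShape,
    s2: NormalizedShape,
    bin_width: float = DEFAULT_BIN_WIDTH,
    indexed: bool = False,
) -> tuple[float, float, np.ndarray]:
    """Per-point contour distances between two normalized shapes.

    For every sample point of each contour the Euclidean distance to the
    nearest point-on-polyline of the other contour is computed (symmetric,
    Hausdorff-style); ``indexed=True`` switches to same-parameter point
    matching instead.  Returns ``(d_avg, d_max, histogram)`` where d_avg is
    the mean and d_max the maximum over both directions, and the histogram
    bins all per-point distances at ``bin_width`` image points.
    """
    if s1.n != s2.n:
        raise ConfigurationError(f"sample counts differ: {s1.n} != {s2.n}")
    d12 = _directed_distances(s1.contour, s2.contour, indexed)
    d21 = _directed_distances(s2.contour, s1.contour, indexed)
    dists = np.concatenate([d12, d21])
    d_avg = float(dists.mean())
    d_max = float(dists.max())
    nbins = max(1, int(np.ceil((d_max + 1e-12) / bin_width)))
    hist, _ = np.histogram(dists, bins=nbins, range=(0.0, nbins * bin_width))
    return d_avg, d_max, hist


def efd_distance(c1: EFDCoefficients, c2: EFDCoefficients, K: int | None = None) -> float:
    """Mean squared coefficient difference over the first K harmonics."""
    if not (c1.normalized and c2.normalized):
        raise ConfigurationError("efd_distance requires normalized coefficients")
    if K is None:
        K = min(c1.K, c2.K)
    if K > c1.K or K > c2.K:
        raise ConfigurationError(f"K={K} exceeds stored harmonics ({c1.K}, {c2.K})")
    diff = c1.harmonics[:K] - c2.harmonics[:K]
    return float(np.sum(diff * diff) / K)


def mirror_shape(s: NormalizedShape) -> NormalizedShape:
    """Reflect a normalized shape about the horizontal symmetry axis."""
    mirrored = s.contour * np.array([1.0, -1.0])
    coeffs = s.coefficients
    # y -> -y negates the c, d coefficient rows
    harm = coeffs.harmonics * np.array([1.0, 1.0, -1.0, -1.0])
    mc = EFDCoefficients(
        harm,
        coeffs.dc * np.array([1.0, -1.0]),
        normalized=coeffs.normalized,
        norm_record={**coeffs.norm_record, "mirrored": True},
    )
    return replace(s, coefficients=mc, contour=mirrored)


def symmetry_error_distance(s: NormalizedShape) -> float:
    """Mean distance from the mirrored contour to the original polyline."""
    mirrored = s.contour * np.array([1.0, -1.0])
    return float(points_to_polyline_distance(mirrored, s.contour).mean())


def _raster_fill(points: np.ndarray, origin: np.ndarray, step: float, shape) -> np.ndarray:
    return fill_polygon((points - origin) / step, shape)


def symmetry_error_area(
    s: NormalizedShape, grid_resolution: int = DEFAULT_GRID_RESOLUTION
) -> float:
    """Mismatch-area ratio: area(XOR of shape and its mirror) / area(shape).

    Region operations are done on a square raster grid of ``grid_resolution``
    pixels spanning the combined bounding box (which is symmetric about the
    axis by construction).
    """
    pts = s.contour
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    # symmetric vertical extent so shape and mirror share the grid
    ymax = max(abs(lo[1]), abs(hi[1]))
    lo = np.array([lo[0], -ymax])
    hi = np.array([hi[0], ymax])
    span = float(np.max(hi - lo))
    step = span / grid_resolution
    if MAJOR_DIAMETER / step < MIN_GRID_ACROSS_AXIS:
        raise ResolutionError(
            f"grid_resolution={grid_resolution} gives fewer than "
            f"{MIN_GRID_ACROSS_AXIS} pixels across the {MAJOR_DIAMETER:g}-point axis"
        )
    pad = 2 * step
    origin = lo - pad
    n_rows = int(np.ceil((hi[1] - lo[1] + 4 * step) / step)) + 1
    n_cols = int(np.ceil((hi[0] - lo[0] + 4 * step) / step)) + 1
    fill = _raster_fill(pts, origin, step, (n_rows, n_cols))
    fill_m = _raster_fill(pts * np.array([1.0, -1.0]), origin, step, (n_rows, n_cols))
    denom = int(fill.sum())
    if denom == 0:
        raise ResolutionError("shape rasterized to an empty region; grid too coarse")
    return float(np.logical_xor(fill, fill_m).sum()) / denom


def compare_pair(
    id1: str,
    area1: float,
    s1: NormalizedShape,
    id2: str,
    area2: float,
    s2: NormalizedShape,
    category: str,
    K: int | None = None,
    bin_width: float = DEFAULT_BIN_WIDTH,
    indexed: bool = False,
) -> PairComparison:
    """Full metric bundle for one leaf pair."""
    d_avg, d_max, hist = contour_distances(s1, s2, bin_width=bin_width, indexed=indexed)
    return PairComparison(
        id1=id1,
        id2=id2,
        category=category,
        delta_area=relative_area_difference(area1, area2),
        d_avg=d_avg,
        d_max=d_max,
        D2=efd_distance(s1.coefficients, s2.coefficients, K),
        histogram=hist,
        bin_width=bin_width,
    )


def _mean(values, what: str) -> float:
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise DegeneratePopulationError(f"empty population for {what}")
    return float(arr.mean())


def population_ratios(
    pairs_cc: list[PairComparison],
    pairs_ct: list[PairComparison],
    sym_control: list[SymmetryResult],
    sym_touched: list[SymmetryResult],
) -> dict:
    """Cross-category ratio statistics.

    delta_avg, delta_max: mean contour distance of control-control pairs
    over control-touched pairs; delta_efd: sqrt of the analogous ratio of
    mean squared coefficient distances; delta_d, delta_a: touched-over-
    control ratios of the mean symmetry errors.
    """
    def ratio(num: float, den: float, what: str) -> float:
        if den == 0:
            raise DegeneratePopulationError(f"zero denominator in {what}")
        return num / den

    out = {
        "delta_avg": ratio(
            _mean((p.d_avg for p in pairs_cc), "cc d_avg"),
            _mean((p.d_avg for p in pairs_ct), "ct d_avg"),
            "delta_avg",
        ),
        "delta_max": ratio(
            _mean((p.d_max for p in pairs_cc), "cc d_max"),
            _mean((p.d_max for p in pairs_ct), "ct d_max"),
            "delta_max",
        ),
        "delta_efd": float(
            np.sqrt(
                ratio(
                    _mean((p.D2 for p in pairs_cc), "cc D2"),
                    _mean((p.D2 for p in pairs_ct), "ct D2"),
                    "delta_efd",
                )
            )
        ),
        "delta_d": ratio(
            _mean((r.e_d for r in sym_touched), "touched e_d"),
            _mean((r.e_d for r in sym_control), "control e_d"),
            "delta_d",
        ),
        "delta_a": ratio(
            _mean((r.epsilon_a for r in sym_touched), "touched epsilon_a"),
            _mean((r.epsilon_a for r in sym_control), "control epsilon_a"),
            "delta_a",
        ),
    }
    return out
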