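"""Elliptic Fourier analysis of closed contours.

Forward transform, frequency-domain normalization (position, scale,
rotation, starting point) and inverse reconstruction, following the
classic harmonic-ellipse decomposition of chain-coded closed curves.
The parameterization is arc length, so unevenly spaced mask contours
are handled correctly.

Normalization convention: the first-harmonic ellipse is rotated so its
major axis is horizontal and scaled so its major diameter equals
``MAJOR_DIAMETER`` (1000 plane units); the centroid offset is zeroed and
the starting-point phase is rotated to the major-axis end. Reflection is
deliberately NOT normalized — chirality carries the asymmetry signal
that the symmetry metrics measure.
"""

from __future__ import annotations

import csv
import io
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon, box

from leafmorph.errors import ConfigurationError, GeometryError
from leafmorph.geometry import as_contour

log = logging.getLogger(__name__)

MAJOR_DIAMETER = 1000.0
DEFAULT_HARMONICS = 50
DEFAULT_SAMPLES = 1000

__all__ = [
    "EFDCoefficients",
    "NormalizedShape",
    "efd_forward",
    "efd_normalize",
    "efd_inverse",
    "normalized_shape",
    "MAJOR_DIAMETER",
    "DEFAULT_HARMONICS",
    "DEFAULT_SAMPLES",
]


@dataclass
class EFDCoefficients:
    """Per-harmonic quadruples (a, b, c, d) plus the DC (centroid) offset.

    ``harmonics`` has shape (K, 4); row i-1 holds the coefficients of
    harmonic i.  ``norm_record`` stores the similarity transform applied
    by :func:`efd_normalize` (empty for raw coefficients).
    """

    harmonics: np.ndarray
    dc: np.ndarray
    normalized: bool = False
    norm_record: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.harmonics = np.asarray(self.harmonics, dtype=float)
        self.dc = np.asarray(self.dc, dtype=float)
        if self.harmonics.ndim != 2 or self.harmonics.shape[1] != 4 or self.harmonics.shape[0] < 1:
            raise ConfigurationError(f"harmonics must be (K>=1, 4), got {self.harmonics.shape}")
        if self.dc.shape != (2,):
            raise ConfigurationError("dc offset must be a length-2 vector")

    @property
    def K(self) -> int:
        return self.harmonics.shape[0]

    def to_csv(self) -> str:
        """Serialize as CSV: a header comment row with the normalization
        record, then one ``i,a,b,c,d`` row per harmonic."""
        buf = io.StringIO()
        w = csv.writer(buf)
        rec = self.norm_record
        w.writerow(
            [
                "# K", self.K,
                "A0", repr(float(self.dc[0])),
                "C0", repr(float(self.dc[1])),
                "normalized", int(self.normalized),
                "scale", repr(float(rec.get("scale", 1.0))),
                "rotation", repr(float(rec.get("rotation", 0.0))),
                "shift", repr(float(rec.get("shift", 0.0))),
            ]
        )
        w.writerow(["i", "a", "b", "c", "d"])
        for i, row in enumerate(self.harmonics, start=1):
            w.writerow([i] + [repr(float(v)) for v in row])
        return buf.getvalue()

    @classmethod
    def from_csv(cls, text: str) -> "EFDCoefficients":
        rows = list(csv.reader(io.StringIO(text)))
        meta = rows[0]
        kv = dict(zip(meta[0::2], meta[1::2]))
        dc = np.array([float(kv["A0"]), float(kv["C0"])])
        normalized = bool(int(kv.get("normalized", 0)))
        rec = {}
        if normalized:
            rec = {
                "scale": float(kv.get("scale", 1.0)),
                "rotation": float(kv.get("rotation", 0.0)),
                "shift": float(kv.get("shift", 0.0)),
            }
        harm = np.array([[float(v) for v in row[1:5]] for row in rows[2:] if row])
        return cls(harm, dc, normalized=normalized, norm_record=rec)


@dataclass
class NormalizedShape:
    """Normalized coefficients plus their inverse-reconstructed contour.

    The contour is sampled at ``n`` uniformly spaced parameter values, so
    point k of any two shapes in one analysis corresponds to the same
    parameter; the symmetry axis is the horizontal line y = 0.
    """

    coefficients: EFDCoefficients
    contour: np.ndarray
    n: int

    def __post_init__(self) -> None:
        if not self.coefficients.normalized:
            raise ConfigurationError("NormalizedShape requires normalized coefficients")


def efd_forward(
    contour, K: int = DEFAULT_HARMONICS, parameterization: str = "arc"
) -> EFDCoefficients:
    """Forward elliptic Fourier transform of a closed polygon.

    The polygon is traversed edge by edge; coefficients are exact for the
    piecewise-linear curve (no quadrature). ``parameterization`` selects
    the curve parameter: ``"arc"`` (cumulative chord length — correct for
    unevenly spaced mask contours, the pipeline default) or ``"uniform"``
    (one parameter step per vertex — under which a polygon sampled from
    ``x = A cos t, y = B sin t`` at uniform t is the exact first-harmonic
    primitive).
    """
    pts = as_contour(contour)
    if K < 1:
        raise ConfigurationError("K must be >= 1")
    if parameterization not in ("arc", "uniform"):
        raise ConfigurationError(f"unknown parameterization {parameterization!r}")
    closed = np.vstack([pts, pts[:1]])
    d = np.diff(closed, axis=0)  # (M, 2) edge vectors
    chord = np.hypot(d[:, 0], d[:, 1])
    keep = chord > 0
    d = d[keep]
    dt = chord[keep] if parameterization == "arc" else np.ones(int(keep.sum()))
    if len(dt) < 3:
        raise GeometryError("degenerate contour: fewer than 3 distinct vertices")
    T = float(dt.sum())
    if T <= 0:
        raise GeometryError("zero-perimeter contour")
    t1 = np.concatenate([[0.0], np.cumsum(dt)])  # (M+1,)
    phi = 2.0 * np.pi * t1 / T

    n = np.arange(1, K + 1)[:, None]  # (K, 1)
    cos_term = np.cos(n * phi[1:]) - np.cos(n * phi[:-1])  # (K, M)
    sin_term = np.sin(n * phi[1:]) - np.sin(n * phi[:-1])
    scale = T / (2.0 * (n.ravel() ** 2) * np.pi**2)  # (K,)
    slope = d / dt[:, None]  # (M, 2) dx/dt, dy/dt

    a = scale * (cos_term @ slope[:, 0])
    b = scale * (sin_term @ slope[:, 0])
    c = scale * (cos_term @ slope[:, 1])
    dd = scale * (sin_term @ slope[:, 1])

    # DC offset = arc-length mean of the piecewise-linear curve (exact)
    starts = closed[:-1][keep]
    mids = starts + 0.5 * d
    dc = (mids * dt[:, None]).sum(axis=0) / T

    return EFDCoefficients(np.column_stack([a, b, c, dd]), dc)


def _rotate_start(harm: np.ndarray, theta: float) -> np.ndarray:
    """Shift the starting point by parameter angle theta (per-harmonic
    right-multiplication by a rotation of angle i*theta)."""
    K = harm.shape[0]
    i = np.arange(1, K + 1)
    c, s = np.cos(i * theta), np.sin(i * theta)
    a, b, cc, d = harm.T
    return np.column_stack(
        [a * c + b * s, -a * s + b * c, cc * c + d * s, -cc * s + d * c]
    )


def _rotate_plane(harm: np.ndarray, psi: float) -> np.ndarray:
    """Rotate the shape in the plane by -psi (left-multiplication)."""
    c, s = np.cos(psi), np.sin(psi)
    a, b, cc, d = harm.T
    return np.column_stack(
        [c * a + s * cc, c * b + s * d, -s * a + c * cc, -s * b + c * d]
    )


def _candidate(harm: np.ndarray, theta: float) -> tuple[np.ndarray, float, float]:
    h = _rotate_start(harm, theta)
    psi = float(np.arctan2(h[0, 2], h[0, 0]))
    h = _rotate_plane(h, psi)
    semi_major = h[0, 0]
    return h, psi, semi_major


def _upper_lobe_area(points: np.ndarray) -> float:
    poly = Polygon(points)
    if not poly.is_valid:
        poly = poly.buffer(0)
    minx, miny, maxx, maxy = poly.bounds
    pad = 1.0 + max(maxx - minx, maxy - miny)
    upper = box(minx - pad, 0.0, maxx + pad, maxy + pad)
    return float(poly.intersection(upper).area)


def efd_normalize(coeffs: EFDCoefficients, _lobe_samples: int = 256) -> EFDCoefficients:
    """Normalize coefficients for position, scale, rotation and start point.

    The residual 180-degree ambiguity of major-axis alignment is resolved
    by preferring the candidate whose contour point at t = 0 has x > 0 and,
    tie-breaking, whose heavier lobe (larger enclosed area) lies above the
    symmetry axis. The applied transform is stored in ``norm_record``.
    """
    harm = coeffs.harmonics
    a1, b1, c1, d1 = harm[0]
    if a1 * a1 + b1 * b1 + c1 * c1 + d1 * d1 == 0.0:
        raise GeometryError("zero first harmonic cannot be normalized")
    denom = a1 * a1 + c1 * c1 - b1 * b1 - d1 * d1
    num = 2.0 * (a1 * b1 + c1 * d1)
    energy = a1 * a1 + b1 * b1 + c1 * c1 + d1 * d1
    if np.hypot(num, denom) < 1e-9 * energy:
        warnings.warn(
            "circular first harmonic: orientation is ambiguous, using phase 0",
            stacklevel=2,
        )
    theta0 = 0.5 * np.arctan2(num, denom)

    best = None
    for theta in (theta0, theta0 + np.pi):
        h, psi, semi_major = _candidate(harm, theta)
        if semi_major <= 0:
            continue
        scale = (MAJOR_DIAMETER / 2.0) / semi_major
        h_scaled = h * scale
        ring = efd_inverse(
            EFDCoefficients(h_scaled, np.zeros(2), normalized=True), _lobe_samples
        )
        x0 = float(ring[0, 0])
        lobe = _upper_lobe_area(ring)
        total = abs(Polygon(ring).area) or 1.0
        cand = {
            "harm": h_scaled,
            "theta": theta,
            "psi": psi,
            "scale": scale,
            "x0": x0,
            "lobe_frac": lobe / total,
        }
        if best is None:
            best = cand
            continue
        # prefer x(0) > 0; tie-break on heavier lobe above the axis
        key_new = (cand["x0"] > 0, cand["lobe_frac"])
        key_old = (best["x0"] > 0, best["lobe_frac"])
        if key_new > key_old:
            best = cand
    if best is None:  # pragma: no cover - defensive
        raise GeometryError("normalization failed: no valid orientation candidate")

    rec = {
        "scale": best["scale"],
        "rotation": -best["psi"],
        "shift": float(np.mod(best["theta"], 2.0 * np.pi)),
        "lobe_above_frac": best["lobe_frac"],
    }
    return EFDCoefficients(best["harm"], np.zeros(2), normalized=True, norm_record=rec)


def efd_inverse(coeffs: EFDCoefficients, n: int = DEFAULT_SAMPLES) -> np.ndarray:
    """Reconstruct a contour at n uniformly spaced parameter values."""
    if n < 8:
        raise ConfigurationError("n must be >= 8")
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    i = np.arange(1, coeffs.K + 1)[:, None]
    cos_it = np.cos(i * t)  # (K, n)
    sin_it = np.sin(i * t)
    a, b, c, d = coeffs.harmonics.T
    x = coeffs.dc[0] + a @ cos_it + b @ sin_it
    y = coeffs.dc[1] + c @ cos_it + d @ sin_it
    return np.column_stack([x, y])


def normalized_shape(
    contour,
    K: int = DEFAULT_HARMONICS,
    n: int = DEFAULT_SAMPLES,
    parameterization: str = "arc",
) -> NormalizedShape:
    """Forward + normalize + inverse: the full shape-standardization chain."""
    coeffs = efd_normalize(efd_forward(contour, K, parameterization))
    return NormalizedShape(coeffs, efd_inverse(coeffs, n), n)
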