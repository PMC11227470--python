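"""Single-leaf scan preprocessing: luminance, Otsu mask, cleanup, contour.

The chain mirrors the classic scanner workflow: RGB scan -> BT.601 luminance
-> Otsu binarization (darker class = leaf on a white background) -> hole
filling and speck removal -> outer contour polygon -> physical area.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage import measure

from leafmorph.errors import (
    CalibrationError,
    DegenerateHistogramError,
    FormatError,
    NoLeafFoundError,
)
from leafmorph.geometry import as_contour, canonical_start, ensure_orientation, fill_polygon

__all__ = [
    "LeafMask",
    "to_luminance",
    "otsu_threshold",
    "otsu_binarize",
    "clean_mask",
    "extract_contour",
    "remove_petiole",
    "area_cm2",
    "load_image",
    "measure_mask_from_image",
]

DEFAULT_MIN_COMPONENT_PX = 100


@dataclass
class LeafMask:
    """Binary leaf mask (foreground = leaf) with dpi calibration.

    ``provenance`` accumulates one entry per processing step applied.
    """

    mask: np.ndarray
    dpi: float
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise FormatError("mask must be 2-D")

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())

    def with_step(self, mask: np.ndarray, step: str) -> "LeafMask":
        return replace(self, mask=mask, provenance=self.provenance + [step])


def to_luminance(image: np.ndarray) -> np.ndarray:
    """BT.601 luminance (the Y of a YUV conversion), rounded to uint8."""
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise FormatError(f"expected a 3-channel color image, got shape {img.shape}")
    rgb = img.astype(np.float64)
    y = 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]
    return np.clip(np.round(y), 0, 255).astype(np.uint8)


def otsu_threshold(gray: np.ndarray) -> int:
    """Otsu's threshold over the 256-bin intensity histogram.

    Returns the integer T maximizing between-class variance for the split
    into classes [0..T] and [T+1..255] (first argmax on ties).
    """
    g = np.asarray(gray)
    if g.ndim != 2:
        raise FormatError("expected a single-channel image")
    hist = np.bincount(g.astype(np.uint8).ravel(), minlength=256).astype(np.float64)
    total = hist.sum()
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogramError("constant image: Otsu threshold undefined")
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(hist)  # weight of class [0..T]
    m0 = np.cumsum(hist * levels)
    w1 = total - w0
    mu0 = np.divide(m0, w0, out=np.zeros(256), where=w0 > 0)
    mu1 = np.divide(m0[-1] - m0, w1, out=np.zeros(256), where=w1 > 0)
    var_between = w0 * w1 * (mu0 - mu1) ** 2
    var_between[w1 == 0] = -1.0  # class split must be non-trivial
    return int(np.argmax(var_between))


def otsu_binarize(gray: np.ndarray, dpi: float = 1200.0) -> LeafMask:
    """Binarize luminance; the darker Otsu class is the leaf foreground."""
    t = otsu_threshold(gray)
    mask = np.asarray(gray) <= t
    return LeafMask(mask, dpi, provenance=[f"otsu threshold={t} foreground=dark"])


def clean_mask(lm: LeafMask, min_component_px: int = DEFAULT_MIN_COMPONENT_PX) -> LeafMask:
    """Fill interior holes, then keep only the largest foreground component.

    Raises :class:`NoLeafFoundError` if nothing at least ``min_component_px``
    pixels large survives.
    """
    filled = ndimage.binary_fill_holes(lm.mask)
    labels, n = ndimage.label(filled)
    if n == 0:
        raise NoLeafFoundError("empty foreground: no leaf found")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    if sizes[largest - 1] < min_component_px:
        raise NoLeafFoundError(
            f"largest component ({int(sizes[largest - 1])} px) below "
            f"min_component_px={min_component_px}"
        )
    out = labels == largest
    return lm.with_step(out, f"clean fill-holes keep-largest min_px={min_component_px}")


def extract_contour(lm: LeafMask) -> np.ndarray:
    """Sub-pixel outer boundary polygon of the (single) mask component.

    Orientation is fixed counter-clockwise as displayed in y-down image
    coordinates (negative shoelace sign) and the starting vertex is the
    lexicographically smallest (y, x) vertex, so repeated runs produce
    identical polygons.
    """
    if not lm.mask.any():
        raise NoLeafFoundError("empty mask has no contour")
    # pad so boundary-touching leaves still produce a closed ring
    padded = np.pad(lm.mask, 1)
    contours = measure.find_contours(padded.astype(float), 0.5)
    if not contours:
        raise NoLeafFoundError("no contour found in mask")
    ring = max(contours, key=len)
    xy = np.column_stack([ring[:, 1], ring[:, 0]]) - 1.0  # (col, row) -> (x, y), unpad
    pts = as_contour(xy)
    return canonical_start(ensure_orientation(pts, positive=False))


def remove_petiole(lm: LeafMask, exclusion, min_component_px: int = DEFAULT_MIN_COMPONENT_PX) -> LeafMask:
    """Erase pixels inside caller-supplied exclusion polygon(s), re-clean.

    ``exclusion`` is one (N, 2) array of (x, y) vertices or a list of them;
    an empty list is the identity.
    """
    polys = exclusion if isinstance(exclusion, (list, tuple)) else [exclusion]
    polys = [p for p in polys if p is not None and len(np.atleast_2d(p)) >= 3]
    if not polys:
        return lm
    out = lm.mask.copy()
    for poly in polys:
        out &= ~fill_polygon(np.asarray(poly, dtype=float), out.shape)
    cleaned = clean_mask(
        lm.with_step(out, f"petiole-exclusion n_polygons={len(polys)}"),
        min_component_px=min_component_px,
    )
    return cleaned


def area_cm2(lm: LeafMask) -> float:
    """Foreground area in cm^2: pixel count x (2.54 / dpi)^2."""
    if lm.dpi is None or lm.dpi <= 0:
        raise CalibrationError(f"invalid dpi: {lm.dpi!r}")
    return lm.pixel_count * (2.54 / lm.dpi) ** 2


def load_image(path, dpi: float | None = None) -> tuple[np.ndarray, float]:
    """Load an RGB image; dpi from file metadata unless overridden."""
    with Image.open(path) as im:
        if dpi is None:
            info = im.info.get("dpi")
            if info:
                dpi = float(info[0])
        arr = np.asarray(im.convert("RGB"))
    if dpi is None or dpi <= 0:
        raise CalibrationError(f"no dpi metadata in {path}; pass dpi explicitly")
    return arr, dpi


def measure_mask_from_image(
    image: np.ndarray,
    dpi: float,
    petiole_exclusion=None,
    min_component_px: int = DEFAULT_MIN_COMPONENT_PX,
) -> LeafMask:
    """Full preprocessing chain: luminance -> Otsu -> clean (-> de-petiole)."""
    lm = clean_mask(otsu_binarize(to_luminance(image), dpi), min_component_px)
    if petiole_exclusion is not None:
        lm = remove_petiole(lm, petiole_exclusion, min_component_px)
    return lm
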