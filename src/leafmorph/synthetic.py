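"""Synthetic leaf-scan generator.

Produces single-leaf scanner-style images plus a pairing manifest with the
same statistical structure the analysis pipeline assumes: two treatment
groups x three node levels x replicate plants x two leaves per node, with
configurable per-node area effects and a configurable ratio of expected
axial-symmetry error between the groups.

The base outline lives directly in elliptic-Fourier coefficient space
(low harmonics: ovate body and acute tip; one high harmonic: margin
serration), so ground truth is expressed in the same basis the measurement
pipeline uses. Asymmetry is injected as a normal-displacement field that
is an odd function of the contour parameter about the tip-to-base axis,
which breaks mirror symmetry by construction and scales both symmetry
errors monotonically.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from shapely.geometry import Polygon

from leafmorph.errors import CanvasOverflowError, InvalidShapeError
from leafmorph.geometry import fill_polygon, signed_area

__all__ = [
    "LeafShapeParams",
    "StudyDesign",
    "make_leaf_outline",
    "rasterize_leaf",
    "ground_truth_mask",
    "generate_manifest",
    "generate_study",
    "MANIFEST_COLUMNS",
]

MANIFEST_COLUMNS = [
    "plant_id",
    "node",
    "treatment",
    "leaf_index",
    "path",
    "true_area_cm2",
    "true_asym",
]

# symmetric nettle-like base: x even / y odd in the contour parameter
# (harmonic index, a_i, d_i); harmonic 1 is the ovate body ellipse
_BASE_COEFFICIENTS = (
    (1, 1.00, 0.55),
    (2, -0.13, 0.0),
    (3, 0.06, -0.05),
    (4, -0.02, 0.0),
)
_SERRATION_HARMONIC = 15
_OUTLINE_SAMPLES = 1024
_LEAF_RGB = (58, 112, 66)
_BACKGROUND_GRAY = 250


@dataclass
class LeafShapeParams:
    """Parameters of one synthetic leaf outline."""

    area_cm2: float
    asymmetry_magnitude: float = 0.0
    serration_depth: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0
    jitter: float = 0.0  # relative perturbation of the base harmonics
    base_coefficients: tuple = _BASE_COEFFICIENTS

    def validate(self) -> None:
        if self.area_cm2 <= 0:
            raise InvalidShapeError(f"area_cm2 must be > 0, got {self.area_cm2}")
        if self.asymmetry_magnitude < 0:
            raise InvalidShapeError("asymmetry_magnitude must be >= 0")
        if self.serration_depth < 0:
            raise InvalidShapeError("serration_depth must be >= 0")


@dataclass
class StudyDesign:
    """Layout and effect sizes of a full synthetic study."""

    n_plants_per_group: int = 7
    nodes: tuple = ("a", "b", "c")
    leaves_per_node: int = 2
    area_means_control: tuple = (4.67, 22.61, 23.96)
    area_effect: tuple = (1.0, 0.4, 0.4)
    asymmetry_factor: float = 1.6
    within_group_cv: float = 0.5
    control_asymmetry: float = 0.05
    asymmetry_cv: float = 0.3
    serration_depth: float = 0.004
    shape_jitter: float = 0.05
    noise_sd: float = 3.0
    dpi: float = 1200.0
    image_format: str = "png"  # "png" (lossless) or "jpeg" (quality 95)
    master_seed: int = 0

    @property
    def n_images(self) -> int:
        return self.n_plants_per_group * 2 * len(self.nodes) * self.leaves_per_node


def _base_series(params: LeafShapeParams, rng: np.random.Generator) -> np.ndarray:
    """Evaluate the symmetric base outline (x even, y odd in t)."""
    t = np.linspace(0.0, 2.0 * np.pi, _OUTLINE_SAMPLES, endpoint=False)
    x = np.zeros_like(t)
    y = np.zeros_like(t)
    for i, a_i, d_i in params.base_coefficients:
        if params.jitter > 0 and i > 1:
            a_i = a_i * (1.0 + params.jitter * rng.standard_normal())
            d_i = d_i * (1.0 + params.jitter * rng.standard_normal())
        x += a_i * np.cos(i * t)
        y += d_i * np.sin(i * t)
    if params.serration_depth > 0:
        h = _SERRATION_HARMONIC
        x += params.serration_depth * np.cos(h * t)
        y += params.serration_depth * np.sin(h * t)
    return np.column_stack([x, y])


def make_leaf_outline(params: LeafShapeParams, dpi: float = 1200.0) -> np.ndarray:
    """Closed simple outline polygon in pixel coordinates at the given dpi.

    The enclosed polygon area matches ``area_cm2`` exactly at the stated
    dpi (the outline is rescaled after all perturbations). Deterministic
    for fixed params.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    pts = _base_series(params, rng)

    if params.asymmetry_magnitude > 0:
        t = np.linspace(0.0, 2.0 * np.pi, _OUTLINE_SAMPLES, endpoint=False)
        tangent = (np.roll(pts, -1, axis=0) - np.roll(pts, 1, axis=0)) / 2.0
        norm = np.hypot(tangent[:, 0], tangent[:, 1])
        normal = np.column_stack([tangent[:, 1], -tangent[:, 0]]) / norm[:, None]
        # odd displacement field about the (horizontal) tip-to-base axis
        amplitude = params.asymmetry_magnitude * (np.sin(t) + 0.35 * np.sin(2 * t))
        pts = pts + amplitude[:, None] * normal

    area_now = abs(signed_area(pts))
    if area_now <= 0:
        raise InvalidShapeError("degenerate outline: zero enclosed area")
    target_px = params.area_cm2 * (dpi / 2.54) ** 2
    pts = pts * np.sqrt(target_px / area_now)

    poly = Polygon(pts)
    if not (poly.is_valid and poly.is_simple):
        raise InvalidShapeError(
            "self-intersecting outline; reduce asymmetry_magnitude="
            f"{params.asymmetry_magnitude} or serration_depth={params.serration_depth}"
        )
    # shift into the positive quadrant with a margin
    margin = 0.05 * np.ptp(pts, axis=0).max() + 4.0
    pts = pts - pts.min(axis=0) + margin
    return pts


def ground_truth_mask(outline: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Rasterized fill of the outline — the mask the pipeline should recover."""
    return fill_polygon(outline, shape)


def _canvas_shape(outline: np.ndarray) -> tuple[int, int]:
    margin = 0.05 * np.ptp(outline, axis=0).max() + 4.0
    h = int(np.ceil(outline[:, 1].max() + margin))
    w = int(np.ceil(outline[:, 0].max() + margin))
    return h, w


def rasterize_leaf(
    outline: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
    canvas_shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Render the filled outline as a scanner-style RGB image.

    Near-white background, darker green leaf, optional additive Gaussian
    intensity noise. Deterministic for a fixed seed.
    """
    if canvas_shape is None:
        canvas_shape = _canvas_shape(outline)
    h, w = canvas_shape
    if outline[:, 0].min() < 0 or outline[:, 1].min() < 0 or outline[:, 0].max() >= w or outline[:, 1].max() >= h:
        raise CanvasOverflowError(
            f"outline bounds exceed canvas {canvas_shape}"
        )
    mask = ground_truth_mask(outline, (h, w))
    img = np.full((h, w, 3), _BACKGROUND_GRAY, dtype=np.float64)
    img[mask] = _LEAF_RGB
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img += rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def _lognormal(rng: np.random.Generator, mean: float, cv: float) -> float:
    """Draw from a log-normal with the given mean and coefficient of variation."""
    if cv <= 0:
        return mean
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, np.sqrt(sigma2)))


def generate_manifest(design: StudyDesign) -> list[dict]:
    """Draw the per-leaf ground truth (no images) for a study design.

    One RNG stream per leaf, derived from ``master_seed`` and a leaf
    counter, so each leaf is reproducible independently of generation order.
    """
    rows = []
    counter = 0
    for treatment in ("control", "touched"):
        for plant in range(1, design.n_plants_per_group + 1):
            for node_idx, node in enumerate(design.nodes):
                for leaf_index in range(design.leaves_per_node):
                    rng = np.random.default_rng([design.master_seed, counter])
                    mean_area = design.area_means_control[node_idx]
                    mean_asym = design.control_asymmetry
                    if treatment == "touched":
                        mean_area *= design.area_effect[node_idx]
                        mean_asym *= design.asymmetry_factor
                    area = _lognormal(rng, mean_area, design.within_group_cv)
                    asym = _lognormal(rng, mean_asym, design.asymmetry_cv)
                    node_label = node.upper() if treatment == "control" else node.lower()
                    ext = "jpg" if design.image_format == "jpeg" else "png"
                    rows.append(
                        {
                            "plant_id": f"{treatment[:1]}{plant:02d}",
                            "node": node_label,
                            "treatment": treatment,
                            "leaf_index": leaf_index,
                            "path": f"{treatment[:1]}{plant:02d}_{node_label}_{leaf_index}.{ext}",
                            "true_area_cm2": area,
                            "true_asym": asym,
                            "shape_seed": int(rng.integers(0, 2**31 - 1)),
                            "noise_seed": int(rng.integers(0, 2**31 - 1)),
                        }
                    )
                    counter += 1
    return rows


def leaf_outline_for_row(row: dict, design: StudyDesign) -> np.ndarray:
    params = LeafShapeParams(
        area_cm2=row["true_area_cm2"],
        asymmetry_magnitude=row["true_asym"],
        serration_depth=design.serration_depth,
        seed=row["shape_seed"],
        jitter=design.shape_jitter,
    )
    return make_leaf_outline(params, dpi=design.dpi)


def generate_study(design: StudyDesign, out_dir) -> Path:
    """Write one image per leaf plus ``manifest.csv``; returns the manifest path.

    Byte-identical output for a fixed ``master_seed``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = generate_manifest(design)
    for row in rows:
        outline = leaf_outline_for_row(row, design)
        img = rasterize_leaf(outline, noise_sd=design.noise_sd, seed=row["noise_seed"])
        if design.image_format == "jpeg":
            Image.fromarray(img).save(out / row["path"], format="JPEG", quality=95)
        else:
            Image.fromarray(img).save(out / row["path"], format="PNG")
    manifest_path = out / "manifest.csv"
    with open(manifest_path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=MANIFEST_COLUMNS, extrasaction="ignore")
        w.writeheader()
        for row in rows:
            w.writerow({**row, "true_area_cm2": repr(row["true_area_cm2"]), "true_asym": repr(row["true_asym"])})
    return manifest_path
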