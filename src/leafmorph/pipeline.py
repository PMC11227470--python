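"""End-to-end study runner: measure every leaf, build pairings, aggregate.

Pairing scheme: a touched leaf is paired with the control leaf from the
corresponding node of the matching replicate plant ("ct" pairs); control
leaves from the same node are additionally paired randomly without
replacement against each other ("cc" pairs) to estimate natural variation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from leafmorph.config import RunConfig
from leafmorph.efd import NormalizedShape, normalized_shape
from leafmorph.errors import IncompleteDesignError, LeafmorphError
from leafmorph.metrics import (
    SymmetryResult,
    compare_pair,
    population_ratios,
    symmetry_error_area,
    symmetry_error_distance,
)
from leafmorph.preprocessing import area_cm2, extract_contour, load_image, measure_mask_from_image
from leafmorph.stats import PopulationSummary, build_summary

log = logging.getLogger(__name__)

__all__ = ["LeafMeasurement", "measure_image", "measure_study", "build_pairings", "analyze_study"]


@dataclass
class LeafMeasurement:
    """One leaf's identity plus its mask-derived measurements and shape."""

    leaf_id: str
    plant_id: str
    node: str
    treatment: str
    area_cm2: float
    e_d: float
    epsilon_a: float
    shape: NormalizedShape


def measure_image(image: np.ndarray, dpi: float, config: RunConfig, petiole_exclusion=None):
    """Mask -> contour -> normalized shape -> (area, e_d, epsilon_a, shape)."""
    mask = measure_mask_from_image(
        image, dpi, petiole_exclusion=petiole_exclusion,
        min_component_px=config.min_component_px,
    )
    contour = extract_contour(mask)
    shape = normalized_shape(contour, K=config.harmonics, n=config.contour_samples)
    return {
        "area_cm2": area_cm2(mask),
        "e_d": symmetry_error_distance(shape),
        "epsilon_a": symmetry_error_area(shape, grid_resolution=config.grid_resolution),
        "shape": shape,
        "mask": mask,
        "contour": contour,
    }


def measure_study(images_dir, manifest: pd.DataFrame, config: RunConfig):
    """Measure every manifest row; per-leaf failures are flagged, not fatal.

    Returns ``(measurements, failures)`` where measurements is a list of
    :class:`LeafMeasurement`.
    """
    images_dir = Path(images_dir)
    measurements: list[LeafMeasurement] = []
    failures: list[dict] = []
    for _, row in manifest.iterrows():
        leaf_id = f"{row['plant_id']}/{row['node']}/{row['leaf_index']}"
        try:
            image, dpi = load_image(images_dir / row["path"], dpi=config.dpi)
            m = measure_image(image, dpi, config)
        except (LeafmorphError, OSError) as exc:
            log.warning("leaf %s failed: %s", leaf_id, exc)
            failures.append({"leaf_id": leaf_id, "path": row["path"], "error": str(exc)})
            continue
        measurements.append(
            LeafMeasurement(
                leaf_id=leaf_id,
                plant_id=row["plant_id"],
                node=str(row["node"]).lower(),
                treatment=row["treatment"],
                area_cm2=m["area_cm2"],
                e_d=m["e_d"],
                epsilon_a=m["epsilon_a"],
                shape=m["shape"],
            )
        )
        log.info("leaf %s measured: area=%.3f cm2", leaf_id, m["area_cm2"])
    return measurements, failures


def measurements_frame(measurements) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "leaf_id": m.leaf_id,
                "plant_id": m.plant_id,
                "node": m.node,
                "treatment": m.treatment,
                "area_cm2": m.area_cm2,
                "e_d": m.e_d,
                "epsilon_a": m.epsilon_a,
            }
            for m in measurements
        ]
    )


def build_pairings(measurements, seed: int = 0):
    """Control-touched ("ct") and control-control ("cc") pair index lists.

    ct: within each node, control and touched leaves are matched by
    replicate-plant rank and leaf index. cc: within each node, control
    leaves are paired randomly without replacement (seeded).
    """
    rng = np.random.default_rng(seed)
    by_node: dict[str, dict[str, list]] = {}
    for m in measurements:
        by_node.setdefault(m.node, {}).setdefault(m.treatment, []).append(m)

    ct_pairs, cc_pairs = [], []
    for node in sorted(by_node):
        groups = by_node[node]
        if "control" not in groups or "touched" not in groups:
            raise IncompleteDesignError(f"node {node!r} lacks a treatment group")
        ctrl = sorted(groups["control"], key=lambda m: m.leaf_id)
        touch = sorted(groups["touched"], key=lambda m: m.leaf_id)
        if len(ctrl) != len(touch):
            raise IncompleteDesignError(
                f"node {node!r}: {len(ctrl)} control vs {len(touch)} touched leaves"
            )
        ct_pairs.extend(zip(touch, ctrl))
        perm = rng.permutation(len(ctrl))
        for i in range(0, len(perm) - 1, 2):
            cc_pairs.append((ctrl[perm[i]], ctrl[perm[i + 1]]))
    return cc_pairs, ct_pairs


def analyze_study(measurements, config: RunConfig, pair_seed: int = 0) -> tuple[pd.DataFrame, PopulationSummary]:
    """Pair, compute all pairwise metrics and build the population summary."""
    cc_pairs, ct_pairs = build_pairings(measurements, seed=pair_seed)

    def run_pairs(pairs, category):
        out = []
        for m1, m2 in pairs:
            out.append(
                (
                    m1.node,
                    compare_pair(
                        m1.leaf_id, m1.area_cm2, m1.shape,
                        m2.leaf_id, m2.area_cm2, m2.shape,
                        category,
                        K=config.harmonics,
                        bin_width=config.bin_width,
                        indexed=(config.distance_pairing == "indexed"),
                    ),
                )
            )
        return out

    cc = run_pairs(cc_pairs, "cc")
    ct = run_pairs(ct_pairs, "ct")
    pair_rows = [
        {
            "id1": p.id1,
            "id2": p.id2,
            "node": node,
            "category": p.category,
            "delta_area": p.delta_area,
            "d_avg": p.d_avg,
            "d_max": p.d_max,
            "D2": p.D2,
        }
        for node, p in cc + ct
    ]
    pairs_df = pd.DataFrame(pair_rows)

    sym_control = [
        SymmetryResult(m.leaf_id, m.e_d, m.epsilon_a)
        for m in measurements
        if m.treatment == "control"
    ]
    sym_touched = [
        SymmetryResult(m.leaf_id, m.e_d, m.epsilon_a)
        for m in measurements
        if m.treatment == "touched"
    ]
    ratios = population_ratios(
        [p for _, p in cc], [p for _, p in ct], sym_control, sym_touched
    )
    summary = build_summary(
        measurements_frame(measurements),
        pairs_df,
        ratios,
        alpha=config.alpha,
        force_test=config.force_test,
    )
    return pairs_df, summary
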