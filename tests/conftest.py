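import numpy as np
import pytest

from leafmorph.config import RunConfig
from leafmorph.synthetic import LeafShapeParams, StudyDesign, make_leaf_outline


def ellipse(A=3.0, B=1.3, m=4096, phase=0.0, center=(0.0, 0.0), rotation=0.0):
    """Polygon sampled from x = A cos t, y = B sin t at uniform t, CCW."""
    t = np.linspace(0.0, 2.0 * np.pi, m, endpoint=False) + phase
    pts = np.column_stack([A * np.cos(t), B * np.sin(t)])
    if rotation:
        c, s = np.cos(rotation), np.sin(rotation)
        pts = pts @ np.array([[c, s], [-s, c]])
    return pts + np.asarray(center)


@pytest.fixture
def ellipse_factory():
    return ellipse


@pytest.fixture
def leaf_outline_factory():
    def make(area_cm2=20.0, asym=0.0, serration=0.004, seed=0, dpi=150.0, jitter=0.05):
        params = LeafShapeParams(
            area_cm2=area_cm2,
            asymmetry_magnitude=asym,
            serration_depth=serration,
            seed=seed,
            jitter=jitter,
        )
        return make_leaf_outline(params, dpi=dpi)

    return make


@pytest.fixture
def fast_config():
    """Reduced-resolution analysis config used by study-level tests."""
    return RunConfig(dpi=150.0, contour_samples=500, grid_resolution=1024)


@pytest.fixture
def small_design():
    """Tiny study (2 plants/group, 24 leaves) that runs in seconds."""
    return StudyDesign(n_plants_per_group=2, dpi=96.0, master_seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
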