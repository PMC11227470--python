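import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import Polygon

from leafmorph.efd import EFDCoefficients, NormalizedShape, efd_inverse, normalized_shape
from leafmorph.errors import ConfigurationError, DegeneratePopulationError, ResolutionError
from leafmorph.geometry import signed_area
from leafmorph.metrics import (
    PairComparison,
    SymmetryResult,
    contour_distances,
    efd_distance,
    mirror_shape,
    population_ratios,
    relative_area_difference,
    symmetry_error_area,
    symmetry_error_distance,
)


def shape_from_coeffs(harmonics, n=1000):
    c = EFDCoefficients(np.asarray(harmonics, dtype=float), np.zeros(2), normalized=True)
    return NormalizedShape(c, efd_inverse(c, n), n)


def ellipse_shape(d1=300.0, n=1000):
    return shape_from_coeffs([[500.0, 0.0, 0.0, d1]], n=n)


class TestRelativeAreaDifference:
    def test_identity(self):
        assert relative_area_difference(10.0, 10.0) == 0.0

    def test_hand_arithmetic(self):
        assert relative_area_difference(3.0, 1.0) == pytest.approx(1.0)

    @pytest.mark.parametrize("k", [1.1, 2.0, 5.0])
    def test_closed_form(self, k):
        a = 7.3
        assert relative_area_difference(a, a * k) == pytest.approx(2 * (k - 1) / (k + 1))

    @given(
        a=st.floats(1e-3, 1e6, allow_nan=False),
        b=st.floats(1e-3, 1e6, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_symmetric_and_bounded(self, a, b):
        d = relative_area_difference(a, b)
        assert d == relative_area_difference(b, a)
        assert 0.0 <= d <= 2.0
        if a == b:
            assert d == 0.0

    def test_domain_error(self):
        with pytest.raises(ConfigurationError):
            relative_area_difference(-1.0, 2.0)


class TestContourDistances:
    def test_identity(self):
        s = ellipse_shape()
        d_avg, d_max, hist = contour_distances(s, s)
        assert d_avg == 0.0 and d_max == 0.0
        assert hist[0] == 2 * s.n and hist.sum() == 2 * s.n

    def test_concentric_circles(self):
        s1 = shape_from_coeffs([[500.0, 0.0, 0.0, 500.0]])
        s2 = shape_from_coeffs([[490.0, 0.0, 0.0, 490.0]])
        d_avg, d_max, _ = contour_distances(s1, s2)
        assert d_avg == pytest.approx(10.0, rel=0.01)
        assert d_max == pytest.approx(10.0, rel=0.01)

    def test_swap_symmetry(self, leaf_outline_factory):
        s1 = normalized_shape(leaf_outline_factory(seed=1, asym=0.03), n=500)
        s2 = normalized_shape(leaf_outline_factory(seed=2, asym=0.05), n=500)
        a = contour_distances(s1, s2)
        b = contour_distances(s2, s1)
        assert a[0] == pytest.approx(b[0]) and a[1] == pytest.approx(b[1])

    def test_avg_le_max(self, leaf_outline_factory, rng):
        for seed in range(5):
            s1 = normalized_shape(leaf_outline_factory(seed=seed, asym=0.04), n=500)
            s2 = normalized_shape(leaf_outline_factory(seed=seed + 50, asym=0.02), n=500)
            d_avg, d_max, _ = contour_distances(s1, s2)
            assert d_avg <= d_max

    def test_mismatched_n_raises(self):
        with pytest.raises(ConfigurationError):
            contour_distances(ellipse_shape(n=500), ellipse_shape(n=600))


class TestEfdDistance:
    def test_identity(self):
        s = ellipse_shape()
        assert efd_distance(s.coefficients, s.coefficients) == 0.0

    def test_single_term_algebra(self):
        K = 50
        h1 = np.zeros((K, 4))
        h1[0] = [500.0, 0.0, 0.0, 300.0]
        h2 = h1.copy()
        delta = 2.5
        h2[0, 0] += delta
        c1 = EFDCoefficients(h1, np.zeros(2), normalized=True)
        c2 = EFDCoefficients(h2, np.zeros(2), normalized=True)
        assert efd_distance(c1, c2, K) == pytest.approx(delta**2 / K)

    def test_brute_force_oracle(self, rng):
        K = 50
        for _ in range(10):
            h1 = rng.normal(size=(K, 4))
            h2 = rng.normal(size=(K, 4))
            c1 = EFDCoefficients(h1, np.zeros(2), normalized=True)
            c2 = EFDCoefficients(h2, np.zeros(2), normalized=True)
            # element-by-element loop oracle
            acc = 0.0
            for i in range(K):
                for j in range(4):
                    acc += (h1[i, j] - h2[i, j]) ** 2
            acc /= K
            assert efd_distance(c1, c2, K) == pytest.approx(acc, rel=1e-12)

    def test_k_overflow_raises(self):
        with pytest.raises(ConfigurationError):
            efd_distance(ellipse_shape().coefficients, ellipse_shape().coefficients, K=5)


class TestMirrorShape:
    def test_involution(self, leaf_outline_factory):
        s = normalized_shape(leaf_outline_factory(seed=3, asym=0.05), n=500)
        back = mirror_shape(mirror_shape(s))
        np.testing.assert_allclose(back.contour, s.contour, atol=1e-12)

    def test_ellipse_fixed_point_set(self):
        s = ellipse_shape()
        m = mirror_shape(s)
        # same point set (traversal direction reversed)
        d = np.abs(np.sort(m.contour[:, 1]) - np.sort(s.contour[:, 1]))
        assert d.max() < 1e-9

    def test_signed_area_flips_magnitude_preserved(self, leaf_outline_factory):
        s = normalized_shape(leaf_outline_factory(seed=4, asym=0.06), n=500)
        a0 = signed_area(s.contour)
        a1 = signed_area(mirror_shape(s).contour)
        assert a1 == pytest.approx(-a0, rel=1e-12)

    def test_coefficients_mirrored(self):
        s = ellipse_shape(d1=250.0)
        m = mirror_shape(s)
        assert m.coefficients.harmonics[0, 3] == -250.0


class TestSymmetryErrors:
    def test_ellipse_zero(self):
        s = ellipse_shape()
        assert symmetry_error_distance(s) < 1e-3
        assert symmetry_error_area(s, grid_resolution=1024) < 1e-2

    def test_bump_monotonicity(self, leaf_outline_factory):
        values = []
        for h in (0.02, 0.04, 0.08):
            s = normalized_shape(leaf_outline_factory(seed=11, asym=h, serration=0.0), n=1000)
            values.append(symmetry_error_distance(s))
        assert values[0] < values[1] < values[2]

    def test_rigid_motion_invariance(self, leaf_outline_factory):
        out = leaf_outline_factory(seed=7, asym=0.05)
        s0 = normalized_shape(out, n=1000)
        th = 0.9
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = np.roll(out @ R.T * 1.7 + np.array([300.0, -50.0]), 101, axis=0)
        s1 = normalized_shape(moved, n=1000)
        assert symmetry_error_distance(s1) == pytest.approx(symmetry_error_distance(s0), rel=1e-6)
        assert symmetry_error_area(s1, 1024) == pytest.approx(symmetry_error_area(s0, 1024), rel=1e-3)

    def test_half_disk_extreme(self):
        # region entirely above the axis: XOR = both half-disks, ratio = 2
        t = np.linspace(0.0, np.pi, 400)
        half = np.vstack(
            [
                np.column_stack([500 * np.cos(t), 1.0 + 500 * np.sin(t)]),
                np.array([[-500.0, 1.0], [500.0, 1.0]]),
            ]
        )
        c = EFDCoefficients(np.array([[500.0, 0.0, 0.0, 500.0]]), np.zeros(2), normalized=True)
        s = NormalizedShape(c, half, len(half))
        assert symmetry_error_area(s, grid_resolution=1024) == pytest.approx(2.0, rel=0.02)

    def test_grid_convergence(self, leaf_outline_factory):
        s = normalized_shape(leaf_outline_factory(seed=8, asym=0.05), n=1000)
        e1 = symmetry_error_area(s, grid_resolution=1024)
        e2 = symmetry_error_area(s, grid_resolution=2048)
        assert abs(e2 - e1) / e2 < 0.01

    def test_shapely_oracle(self, leaf_outline_factory):
        s = normalized_shape(leaf_outline_factory(seed=9, asym=0.06), n=1000)
        got = symmetry_error_area(s, grid_resolution=2048)
        poly = Polygon(s.contour)
        mirr = Polygon(s.contour * np.array([1.0, -1.0]))
        oracle = poly.symmetric_difference(mirr).area / poly.area
        assert got == pytest.approx(oracle, rel=0.02)

    def test_resolution_error(self):
        with pytest.raises(ResolutionError):
            symmetry_error_area(ellipse_shape(), grid_resolution=128)

    def test_ed_epsa_rank_correlation(self, leaf_outline_factory):
        from scipy.stats import spearmanr

        eds, eas = [], []
        for i, asym in enumerate(np.linspace(0.0, 0.1, 12)):
            s = normalized_shape(leaf_outline_factory(seed=20 + i, asym=asym), n=500)
            eds.append(symmetry_error_distance(s))
            eas.append(symmetry_error_area(s, grid_resolution=1024))
        rho = spearmanr(eds, eas).statistic
        assert rho > 0.9


class TestPopulationRatios:
    @staticmethod
    def _pair(d_avg, d_max, D2):
        return PairComparison("x", "y", "cc", 0.1, d_avg, d_max, D2)

    def test_single_identical_pair(self):
        p = self._pair(3.0, 5.0, 0.2)
        sym = [SymmetryResult("a", 1.0, 0.5)]
        r = population_ratios([p], [p], sym, sym)
        assert r["delta_avg"] == 1.0 and r["delta_max"] == 1.0
        assert r["delta_efd"] == pytest.approx(1.0)
        assert r["delta_d"] == 1.0 and r["delta_a"] == 1.0

    def test_formulas(self):
        cc = [self._pair(2.0, 4.0, 0.16), self._pair(4.0, 8.0, 0.64)]
        ct = [self._pair(6.0, 12.0, 1.0)]
        sc = [SymmetryResult("c", 2.0, 0.1)]
        st = [SymmetryResult("t", 5.0, 0.3)]
        r = population_ratios(cc, ct, sc, st)
        assert r["delta_avg"] == pytest.approx(3.0 / 6.0)
        assert r["delta_max"] == pytest.approx(6.0 / 12.0)
        assert r["delta_efd"] == pytest.approx(np.sqrt(0.4 / 1.0))
        assert r["delta_d"] == pytest.approx(2.5)
        assert r["delta_a"] == pytest.approx(3.0)

    def test_zero_denominator(self):
        p0 = self._pair(0.0, 0.0, 0.0)
        sym = [SymmetryResult("a", 1.0, 0.5)]
        with pytest.raises(DegeneratePopulationError):
            population_ratios([p0], [p0], sym, sym)

    def test_empty_population(self):
        with pytest.raises(DegeneratePopulationError):
            population_ratios([], [self._pair(1, 2, 3)], [], [])
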