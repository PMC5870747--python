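import math
from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circamoran import (
    DegenerateFieldError,
    PhaseField,
    SpatialField,
    UndefinedCircularMeanError,
    circular_distance,
    circular_mean,
    correlogram,
    grid_locations,
    grid_von_neumann_weights,
    morans_i,
    morans_i_circular,
    null_distribution,
    phase_pattern,
    wrap_angle,
)
from circamoran.weights import WeightMatrix

from conftest import moran_circular_loop, moran_loop, random_weight_matrix

HYP = settings(max_examples=50, derandomize=True, deadline=None)


class TestCircularDistance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (np.pi, -np.pi + 0.01, -0.01),  # geodesic, not 2*pi - 0.01
            (np.pi / 2, 0.0, np.pi / 2),
            (0.3, 0.3, 0.0),
            (-3.0, 3.0, 2 * np.pi - 6.0),
        ],
    )
    def test_signed_shortest_displacement(self, a, b, expected):
        assert circular_distance(a, b) == pytest.approx(expected, abs=1e-12)

    @HYP
    @given(st.floats(-50, 50), st.floats(-50, 50))
    def test_bounded_and_antisymmetric(self, a, b):
        d = circular_distance(a, b)
        assert abs(d) <= np.pi + 1e-12
        if abs(abs(d) - np.pi) > 1e-9:  # antisymmetry breaks only at the cut
            assert circular_distance(b, a) == pytest.approx(-d, abs=1e-9)


class TestCircularMean:
    def test_quarter_circle_pair(self):
        assert circular_mean([0.0, np.pi / 2]) == pytest.approx(np.pi / 4)

    @HYP
    @given(st.floats(-np.pi + 1e-6, np.pi))
    def test_repeated_angle_is_its_own_mean(self, theta):
        assert circular_mean([theta, theta]) == pytest.approx(theta, abs=1e-9)

    def test_antipodal_pair_is_undefined(self):
        with pytest.raises(UndefinedCircularMeanError):
            circular_mean([-np.pi / 2, np.pi / 2])


class TestMoransI:
    def test_checkerboard_is_exactly_minus_one(self, checkerboard10, w10):
        assert morans_i(checkerboard10, w10).statistic == pytest.approx(-1.0, abs=1e-13)

    def test_half_and_half_2x2_is_zero(self):
        W = grid_von_neumann_weights(2, 2, 1)
        fld = SpatialField([1.0, 1.0, 0.0, 0.0])
        assert morans_i(fld, W).statistic == pytest.approx(0.0, abs=1e-13)

    def test_constant_field_raises(self, w10):
        with pytest.raises(DegenerateFieldError):
            morans_i(SpatialField(np.ones(100)), w10)

    def test_unit_count_mismatch_raises(self, w10):
        with pytest.raises(ValueError):
            morans_i(SpatialField(np.arange(9.0)), w10)

    def test_matches_double_loop_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(5, 101))
            W = random_weight_matrix(rng, n)
            x = rng.normal(size=n)
            fast = morans_i(SpatialField(x), W).statistic
            slow = moran_loop(x, W.toarray())
            assert fast == pytest.approx(slow, rel=1e-12)

    @HYP
    @given(st.floats(-10, 10).filter(lambda a: abs(a) > 1e-3), st.floats(-100, 100))
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(7)
        x = rng.normal(size=25)
        W = grid_von_neumann_weights(5, 5, 1)
        base = morans_i(SpatialField(x), W).statistic
        scaled = morans_i(SpatialField(a * x + b), W).statistic
        assert scaled == pytest.approx(base, rel=1e-9, abs=1e-9)

    def test_symmetrization_invariance(self):
        import scipy.sparse as sp

        rng = np.random.default_rng(3)
        W = random_weight_matrix(rng, 30)
        Wsym = WeightMatrix(sp.csr_array((W.matrix + W.matrix.T) * 0.5))
        x = rng.normal(size=30)
        a = morans_i(SpatialField(x), W).statistic
        b = morans_i(SpatialField(x), Wsym).statistic
        assert a == pytest.approx(b, rel=1e-12)

    def test_permutation_mean_exhaustive_n4(self):
        # averaged over all 4! relabelings, I equals -1/(N-1) exactly
        W = grid_von_neumann_weights(2, 2, 1)
        vals = np.array([0.3, 1.7, -0.2, 0.9])
        stats = [
            morans_i(SpatialField(np.array(p)), W).statistic
            for p in permutations(vals)
        ]
        assert np.mean(stats) == pytest.approx(-1.0 / 3.0, abs=1e-12)

    def test_random_relabeling_mean_approaches_analytic_value(self, w10):
        rng = np.random.default_rng(11)
        fld = SpatialField(rng.normal(size=100), locs=grid_locations(10, 10))
        nd = null_distribution(fld, w10, mode="randomize", n_samples=20_000, seed=5)
        se = nd.samples.std(ddof=1) / math.sqrt(nd.n_samples)
        assert nd.samples.mean() == pytest.approx(-1.0 / 99.0, abs=4 * se)


class TestMoransICircular:
    def test_two_phase_checkerboard_is_minus_one(self, checkerboard10, w10):
        # phases {0, pi/2}: circular mean pi/4, deviations -/+ pi/4 — the
        # binary checkerboard structure carries over unchanged
        phases = np.where(checkerboard10.values > 0.5, np.pi / 2, 0.0)
        fld = PhaseField(phases)
        res = morans_i_circular(fld, w10)
        assert res.statistic == pytest.approx(-1.0, abs=1e-12)
        assert res.statistic == pytest.approx(
            moran_circular_loop(phases, w10.toarray()), rel=1e-12
        )

    def test_constant_phases_raise(self, w10):
        with pytest.raises(DegenerateFieldError):
            morans_i_circular(PhaseField(np.full(100, 0.4)), w10)

    def test_balanced_antiphase_field_raises(self):
        W = grid_von_neumann_weights(2, 2, 1)
        with pytest.raises(UndefinedCircularMeanError):
            morans_i_circular(PhaseField([0.0, np.pi, 0.0, np.pi]), W)

    def test_matches_double_loop_oracle_on_random_instances(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            n = int(rng.integers(5, 101))
            W = random_weight_matrix(rng, n)
            theta = rng.vonmises(rng.uniform(-np.pi, np.pi), 2.0, size=n)
            fast = morans_i_circular(PhaseField(theta), W).statistic
            slow = moran_circular_loop(wrap_angle(theta), W.toarray())
            assert fast == pytest.approx(slow, rel=1e-12)

    @HYP
    @given(st.floats(-10, 10))
    def test_rotation_equivariance(self, shift):
        rng = np.random.default_rng(17)
        theta = rng.vonmises(0.5, 3.0, size=36)
        W = grid_von_neumann_weights(6, 6, 1)
        base = morans_i_circular(PhaseField(theta), W).statistic
        rotated = morans_i_circular(PhaseField(wrap_angle(theta + shift)), W).statistic
        assert rotated == pytest.approx(base, abs=1e-9)

    def test_spiral_dissociates_from_kuramoto_order(self):
        from circamoran import kuramoto_order

        fld = phase_pattern(25, 25, "spiral")
        W = grid_von_neumann_weights(25, 25, 1)
        r, _psi = kuramoto_order(fld.phases)
        stat = morans_i_circular(fld, W).statistic
        nd = null_distribution(fld, W, mode="randomize", n_samples=2000, seed=8)
        assert r < 0.2
        assert stat > np.quantile(nd.samples, 0.975)


class TestCorrelogram:
    def test_plane_wave_decays_towards_negative_at_half_wavelength(self):
        # wavelength 16 on 12 columns: phases span 3/4 of the circle, so the
        # circular mean stays defined while lag-8 pairs approach anti-phase
        fld = phase_pattern(12, 12, "plane_wave", wavelength=16.0)
        edges = [0.0, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0]
        bins = correlogram(fld, edges)
        stats = [b.result.statistic for b in bins if not b.empty]
        assert stats[0] > 0.5  # adjacent cells nearly in phase
        assert stats[-1] < 0  # approaching half a wavelength: anti-phase
        assert all(a > b for a, b in zip(stats, stats[1:]))

    def test_random_field_stays_inside_null_band(self, w10):
        rng = np.random.default_rng(23)
        fld = SpatialField(rng.normal(size=100), locs=grid_locations(10, 10))
        nd = null_distribution(fld, w10, mode="randomize", n_samples=2000, seed=3)
        lo, hi = np.quantile(nd.samples, [0.005, 0.995])
        bins = correlogram(fld, [0.0, 1.0, 1.5, 2.0])
        # nulls for band weights differ slightly from w10's, but random data
        # should sit well inside any reasonable band at alpha = 0.01
        for b in bins:
            assert not b.empty
            assert lo - 0.05 < b.result.statistic < hi + 0.05

    def test_single_band_covering_all_pairs_equals_all_ones_weights(self):
        import scipy.sparse as sp

        rng = np.random.default_rng(5)
        fld = SpatialField(rng.normal(size=16), locs=grid_locations(4, 4))
        (bin_,) = correlogram(fld, [0.0, 100.0])
        ones = WeightMatrix(sp.csr_array(1.0 - np.eye(16)))
        assert bin_.result.statistic == pytest.approx(
            morans_i(fld, ones).statistic, rel=1e-12
        )

    def test_empty_bands_are_flagged_not_dropped(self):
        rng = np.random.default_rng(2)
        fld = SpatialField(rng.normal(size=9), locs=grid_locations(3, 3))
        bins = correlogram(fld, [0.0, 1.0, 50.0, 100.0])
        assert [b.empty for b in bins] == [False, False, True]
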