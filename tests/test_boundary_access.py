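"""Lattice first-passage model: analytic oracles, fences, drift."""

import numpy as np
import pytest
from scipy import integrate, special, stats

from tumorfence.boundary_access import (
    ChemotaxisConfig,
    LatticeConfig,
    analytic_denominator,
    analytic_first_passage_density,
    analytic_hit_probability,
    chemotactic_access_ratio,
    make_fence,
    make_hairy_fence,
    nonreflecting_fraction_analytic,
    reflection_histogram,
    simulate_walk,
    simulate_walkers,
    start_grid,
    tumor_access_ratio,
)

CFG = LatticeConfig()


class TestAnalyticOracles:
    def test_half_access_distance(self):
        # 90 μm start, D = 2.5 μm²/min, 2.5 days: 50 % chance of arrival
        assert analytic_hit_probability(90.0, 2.5, 3600.0) == pytest.approx(0.50, abs=0.01)

    def test_boundary_limits(self):
        assert analytic_hit_probability(1e-9, 2.5, 3600.0) == pytest.approx(1.0, abs=1e-6)
        assert analytic_hit_probability(90.0, 2.5, 0.0) == 0.0
        assert analytic_hit_probability(90.0, 2.5, 1e-9) == pytest.approx(0.0, abs=1e-12)

    def test_denominator_single_start(self):
        dm = analytic_denominator([90.0], 2.5, 3600.0, 5000)
        assert dm == pytest.approx(5000 * analytic_hit_probability(90.0, 2.5, 3600.0))
        assert dm == pytest.approx(2500.0, rel=0.01)

    def test_denominator_zero_samples(self):
        assert analytic_denominator([90.0, 50.0], 2.5, 3600.0, 0) == 0.0

    def test_denominator_matches_quadrature_of_current(self):
        # integrate the printed first-passage current numerically
        D, T = 2.5, 3600.0
        ys = [10.0, 50.0, 90.0]
        quad = sum(
            integrate.quad(
                lambda t, y0=y0: analytic_first_passage_density(t, y0, D), 0, T
            )[0]
            for y0 in ys
        )
        closed = analytic_denominator(ys, D, T, 1)
        assert closed == pytest.approx(quad, rel=1e-6)

    def test_invalid_start_height(self):
        with pytest.raises(ValueError):
            analytic_hit_probability(-5.0, 2.5, 100.0)
        with pytest.raises(ValueError):
            analytic_denominator([10.0, -1.0], 2.5, 100.0, 10)


class TestFenceGeometry:
    def test_linear_fence_occupies_first_row(self):
        f = make_fence(90.0, CFG)
        assert f.n_sites == 9
        assert all(r == 1 for r, _ in f.sites)
        cols = sorted(c for _, c in f.sites)
        assert cols == list(range(cols[0], cols[0] + 9))  # consecutive, centered

    def test_zero_and_full_fences(self):
        assert make_fence(0.0, CFG).n_sites == 0
        assert make_fence(230.0, CFG).n_sites == CFG.n_cols
        with pytest.raises(ValueError):
            make_fence(240.0, CFG)

    def test_hairy_fence_displaces_half_up(self):
        f = make_hairy_fence(20.0, seed=3, config=CFG)
        rows = sorted(r for r, _ in f.sites)
        assert rows == [1, 2] and f.n_sites == 2

    def test_hairy_fence_deterministic(self):
        a = make_hairy_fence(90.0, seed=11, config=CFG)
        b = make_hairy_fence(90.0, seed=11, config=CFG)
        assert a.sites == b.sites
        assert sum(1 for r, _ in a.sites if r == 2) == 4  # floor(9/2)

    def test_start_grid_excludes_fence_sites(self):
        f = make_fence(70.0, CFG)
        grid = start_grid(CFG, f)
        full = start_grid(CFG, None)
        assert len(full) == 9 * CFG.n_cols
        assert len(grid) == len(full) - 7
        assert not (set(map(tuple, grid)) & f.sites)


class TestWalkers:
    def test_no_fence_hit_fraction_matches_erfc(self):
        rng = np.random.default_rng(2)
        S = 3000
        hit, _, nref = simulate_walkers(CFG, None, np.array([[3, 5]]), S, rng, T=720.0)
        p = analytic_hit_probability(30.0, CFG.D, 720.0)
        se = np.sqrt(p * (1 - p) / S)
        assert abs(hit.mean() - p) < 3 * se
        assert (nref == 0).all()  # no fence, nothing to reflect off

    def test_first_passage_times_match_analytic_law(self):
        # conditional FPT distribution vs the image-method closed form
        rng = np.random.default_rng(0)
        hit, fpt, _ = simulate_walkers(CFG, None, np.array([[9, 11]]), 5000, rng, T=3600.0)
        samp = fpt[hit]
        norm = special.erfc(90.0 / np.sqrt(4 * CFG.D * 3600.0))
        cdf = lambda t: special.erfc(
            90.0 / np.sqrt(4 * CFG.D * np.clip(t, 1e-9, None))
        ) / norm
        assert stats.kstest(samp, cdf).pvalue > 0.01

    def test_full_width_fence_blocks_every_walker(self):
        f = make_fence(230.0, CFG)
        rng = np.random.default_rng(4)
        hit, _, _ = simulate_walkers(CFG, f, np.array([[5, 0], [3, 12]]), 400, rng, T=720.0)
        assert not hit.any()

    def test_start_inside_fence_rejected(self):
        f = make_fence(90.0, CFG)
        r, c = sorted(f.sites)[0]
        with pytest.raises(ValueError, match="inside the fence"):
            simulate_walk(CFG, f, (r, c), seed=0)
        with pytest.raises(ValueError, match="rows must be >= 1"):
            simulate_walk(CFG, None, (0, 5), seed=0)

    def test_deterministic_under_seed(self):
        f = make_fence(70.0, CFG)
        a = simulate_walk(CFG, f, (2, 11), seed=99, T=720.0)
        b = simulate_walk(CFG, f, (2, 11), seed=99, T=720.0)
        assert a.hit == b.hit and a.n_reflections == b.n_reflections
        assert np.isclose(a.fpt, b.fpt, equal_nan=True)

    def test_drift_calibration_mean_velocity(self):
        # in the drift region the mean descent rate equals v(b)
        rng = np.random.default_rng(7)
        v, T, S = 3.0, 20.0, 4000
        _, _, _, rows = simulate_walkers(
            CFG, None, np.array([[75, 11]]), S, rng, T=T,
            drift_rate=v / CFG.a, drift_rows=CFG.n_rows, return_rows=True,
        )
        dy = (rows - 75) * CFG.a
        per_walker_var = (2 * CFG.D + CFG.a * v) * T  # jump-process variance
        se = np.sqrt(per_walker_var / S)
        assert abs(dy.mean() - (-v * T)) < 3 * se


@pytest.fixture(scope="module")
def short_horizon_scan():
    """Shared fenced runs at T = 0.1 day for the collapse/monotonicity checks."""
    return tumor_access_ratio(
        CFG, [0.0, 30.0, 90.0, 150.0], [144.0], seed=21, S=250
    )


class TestAccessRatio:
    def test_no_fence_ratio_is_unity(self, short_horizon_scan):
        r0 = short_horizon_scan[0]
        se = np.sqrt(r0.n_hit_fence) / r0.n_hit_nofence
        assert r0.b == 0.0
        assert abs(r0.ratio - 1.0) < 3 * se

    def test_full_fence_ratio_is_zero(self):
        res = tumor_access_ratio(CFG, [230.0], [144.0], seed=5, S=50)
        assert res[0].ratio == 0.0

    def test_ratio_non_increasing_in_fence_length(self, short_horizon_scan):
        ratios = [r.ratio for r in short_horizon_scan]
        ses = [
            np.sqrt(max(r.n_hit_fence, 1)) / r.n_hit_nofence
            for r in short_horizon_scan
        ]
        for k in range(len(ratios) - 1):
            assert ratios[k + 1] <= ratios[k] + 3 * (ses[k] + ses[k + 1])

    def test_short_horizon_collapse_onto_diagonal(self, short_horizon_scan):
        # as T shrinks, reflected-and-recovered paths vanish and R_b(T)
        # approaches (L-b)/L
        for r in short_horizon_scan:
            se = np.sqrt(max(r.n_hit_fence, 1)) / r.n_hit_nofence
            expected = nonreflecting_fraction_analytic(r.b, CFG.L)
            assert abs(r.ratio - expected) < 0.02 + 3 * se

    def test_never_reflecting_share_bounded_by_open_fraction(self):
        # with a physically occupying fence, N_nr/N_nf cannot exceed (L-b)/L
        res = tumor_access_ratio(CFG, [90.0], [1440.0], seed=9, S=200)[0]
        se = np.sqrt(max(res.n_nr, 1)) / res.n_hit_nofence
        assert res.n_nr / res.n_hit_nofence <= nonreflecting_fraction_analytic(
            90.0, CFG.L
        ) + 3 * se

    def test_decomposition_identity(self, short_horizon_scan):
        for r in short_horizon_scan:
            assert r.n_nr + r.n_r == r.n_hit_fence

    def test_hairy_fence_reduces_access(self):
        lin = tumor_access_ratio(CFG, [120.0], [1440.0], seed=31, S=250)[0]
        hairy = tumor_access_ratio(CFG, [120.0], [1440.0], seed=31, S=250, hairy=True)[0]
        se = (
            np.sqrt(lin.n_hit_fence) + np.sqrt(hairy.n_hit_fence)
        ) / lin.n_hit_nofence
        assert hairy.ratio <= lin.ratio + 3 * se


class TestNonreflectingAnalytic:
    @pytest.mark.parametrize("b,expected", [(0.0, 1.0), (230.0, 0.0), (90.0, 140 / 230)])
    def test_open_fraction(self, b, expected):
        assert nonreflecting_fraction_analytic(b, 230.0) == pytest.approx(expected)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            nonreflecting_fraction_analytic(231.0, 230.0)


class TestReflectionHistogram:
    def test_no_fence_all_mass_at_zero(self):
        rng = np.random.default_rng(3)
        hit, _, nref = simulate_walkers(CFG, None, np.array([[2, 4]]), 500, rng, T=720.0)
        h = reflection_histogram(hit, nref)
        assert h == {0: 1.0}

    def test_zero_hitters_undefined(self):
        with pytest.raises(ValueError, match="no boundary hitters"):
            reflection_histogram(np.zeros(5, dtype=bool), np.zeros(5, dtype=int))

    def test_reflection_counts_decay_exponentially(self):
        f = make_fence(90.0, CFG)
        rng = np.random.default_rng(6)
        grid = start_grid(CFG, f)
        hit, _, nref = simulate_walkers(CFG, f, grid, 120, rng, T=3600.0)
        h = reflection_histogram(hit, nref)
        ns = np.array(sorted(n for n in h if 1 <= n <= 20 and h[n] > 0))
        logf = np.log([h[n] for n in ns])
        slope, _, r, *_ = stats.linregress(ns, logf)
        assert slope < 0 and r**2 > 0.9


class TestChemotaxis:
    def test_drift_law_saturates(self):
        chemo = ChemotaxisConfig()
        assert chemo.v(0.0) == 0.0
        assert chemo.v(75.0) == pytest.approx(2.5)
        assert chemo.v(150.0) == pytest.approx(5.0)
        assert chemo.v(500.0) == pytest.approx(5.0)  # saturated
        vs = [chemo.v(b) for b in (0, 30, 60, 150, 200)]
        assert vs == sorted(vs)

    def test_no_fence_means_no_drift_ratio_one(self):
        chemo = ChemotaxisConfig()
        res = chemotactic_access_ratio(CFG, chemo, [0.0], T=360.0, seed=8, S=400)[0]
        se = np.sqrt(res.n_hit_fence) / res.n_hit_nofence
        assert abs(res.ratio - 1.0) < 3 * se

    def test_moderate_fence_boosts_access_above_unity(self):
        chemo = ChemotaxisConfig()
        res = chemotactic_access_ratio(CFG, chemo, [40.0], T=720.0, seed=8, S=200)[0]
        assert res.ratio > 1.2

    def test_full_fence_kills_access_despite_drift(self):
        chemo = ChemotaxisConfig()
        res = chemotactic_access_ratio(CFG, chemo, [230.0], T=360.0, seed=8, S=100)[0]
        assert res.ratio == 0.0


def test_lattice_config_validation():
    with pytest.raises(ValueError):
        LatticeConfig(L=235.0)
    with pytest.raises(ValueError):
        LatticeConfig(D=-1.0)
    assert CFG.hop_rate == pytest.approx(0.025)
    assert CFG.n_cols == 23 and CFG.n_rows == 150
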