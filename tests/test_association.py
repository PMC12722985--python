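"""Outcome association: densities, c(r), Ripley's K, t-test, log-rank."""

import numpy as np
import pytest

from tumorfence.association import (
    combined_density_fpm,
    combined_ripley,
    compare_groups_ttest,
    patient_fpm,
    phenotype_density,
    response_correlation,
    ripley_k_cross,
    survival_mean_split_logrank,
    ttest_across_phenotypes,
)
from tumorfence.data import PatientOutcome
from tumorfence.null_model import FpmRecord

from conftest import make_slide


class TestDensity:
    def test_cells_per_mm2(self):
        s = make_slide([(i * 40.0, 0, "g") for i in range(20)])
        assert phenotype_density(s, "g") == pytest.approx(20.0)

    def test_absent_phenotype_zero(self):
        s = make_slide([(0, 0, "other")])
        assert phenotype_density(s, "g") == 0.0

    def test_smaller_area_scales_density(self):
        s = make_slide(
            [(i * 9.0, 0, "g") for i in range(50)], extent=(500.0, 500.0)
        )
        assert phenotype_density(s, "g") == pytest.approx(200.0)


class TestCombinedDensityFpm:
    @pytest.mark.parametrize(
        "sigma_ratio,fpm,r,sign,expected",
        [
            (0.5, 0.3, 0.0, -1, 0.5),  # r=0 reduces to the density term
            (0.0, 0.3, 1.0, -1, -0.3),  # r=1, printed minus sign
            (0.5, 0.3, 0.2, -1, 0.34),  # 0.8*0.5 - 0.2*0.3
            (0.5, 0.3, 0.2, +1, 0.46),  # documented plus variant
        ],
    )
    def test_weighted_combination(self, sigma_ratio, fpm, r, sign, expected):
        c = combined_density_fpm(sigma_ratio, 1.0, fpm, r, sign=sign)
        assert c == pytest.approx(expected)

    def test_invalid_weight_rejected(self):
        with pytest.raises(ValueError):
            combined_density_fpm(0.5, 1.0, 0.3, 1.2)

    def test_correlation_endpoints_match_components(self, rng):
        # c(0) correlates with response exactly as density; c(1) as ∓FPM
        n = 30
        density = rng.uniform(0, 1, n)
        fpm = rng.uniform(0, 1, n)
        codes = rng.integers(0, 2, n)
        while len(set(codes)) < 2:
            codes = rng.integers(0, 2, n)
        c0 = [combined_density_fpm(d, 1.0, m, 0.0) for d, m in zip(density, fpm)]
        c1m = [combined_density_fpm(d, 1.0, m, 1.0, sign=-1) for d, m in zip(density, fpm)]
        c1p = [combined_density_fpm(d, 1.0, m, 1.0, sign=+1) for d, m in zip(density, fpm)]
        assert response_correlation(c0, codes) == pytest.approx(
            response_correlation(density, codes)
        )
        assert response_correlation(c1m, codes) == pytest.approx(
            -response_correlation(fpm, codes)
        )
        assert response_correlation(c1p, codes) == pytest.approx(
            response_correlation(fpm, codes)
        )


class TestResponseCorrelation:
    def test_perfect_agreement(self):
        assert response_correlation([1, 0, 1, 0], [1, 0, 1, 0]) == pytest.approx(1.0)

    def test_perfect_disagreement(self):
        assert response_correlation([0, 1, 0, 1], [1, 0, 1, 0]) == pytest.approx(-1.0)

    def test_null_effect_is_near_zero(self, rng):
        vals = rng.uniform(0, 1, 400)
        codes = rng.integers(0, 2, 400)
        assert abs(response_correlation(vals, codes)) < 0.15

    def test_constant_values_undefined(self):
        with pytest.raises(ValueError, match="constant"):
            response_correlation([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0])

    def test_single_group_undefined(self):
        with pytest.raises(ValueError, match="both"):
            response_correlation([0.1, 0.2, 0.3], [1, 1, 1])


class TestRipleyKCross:
    def test_hand_computed_value(self):
        # 1 a-cell at origin, b-cells at 10 and ~70 μm; only one pair within 30
        s = make_slide(
            [(0, 0, "a"), (10, 0, "b"), (50, 50, "b")], extent=(100.0, 100.0)
        )
        k = ripley_k_cross(s, "a", "b", 30.0)
        assert k.lambda_b == pytest.approx(2e-4)
        assert k.k_value == pytest.approx(5000.0)

    def test_no_neighbors_gives_zero(self):
        s = make_slide([(0, 0, "a"), (90, 90, "b")], extent=(100.0, 100.0))
        assert ripley_k_cross(s, "a", "b", 30.0).k_value == 0.0

    def test_duplicating_b_positions_leaves_k_unchanged(self, rng):
        pts = [(rng.uniform(0, 400), rng.uniform(0, 400), "a") for _ in range(30)]
        pts += [(rng.uniform(0, 400), rng.uniform(0, 400), "b") for _ in range(50)]
        s = make_slide(pts, extent=(400.0, 400.0))
        k1 = ripley_k_cross(s, "a", "b", 30.0)
        doubled = make_slide(
            pts + [(x, y, ph) for x, y, ph in pts if ph == "b"], extent=(400.0, 400.0)
        )
        k2 = ripley_k_cross(doubled, "a", "b", 30.0)
        assert k2.k_value == pytest.approx(k1.k_value)

    def test_matches_all_pairs_oracle(self, rng):
        pts = [(rng.uniform(0, 300), rng.uniform(0, 300), ("a", "b")[rng.integers(2)])
               for _ in range(150)]
        s = make_slide(pts, extent=(300.0, 300.0))
        k = ripley_k_cross(s, "a", "b", 30.0)
        pos = s.positions()
        ph = s.phenotypes()
        a, b = pos[ph == "a"], pos[ph == "b"]
        d = np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(-1))
        count = int((d <= 30.0).sum())
        lam = len(b) / (300.0 * 300.0)
        assert k.k_value == pytest.approx(count / (lam * len(a)))

    def test_missing_phenotype_undefined(self):
        s = make_slide([(0, 0, "a")])
        with pytest.raises(ValueError, match="both phenotypes"):
            ripley_k_cross(s, "a", "b", 30.0)


class TestCombinedRipley:
    def test_endpoint_weights(self):
        assert combined_ripley(3.0, 8.0, 6.0, 16.0, 0.0) == pytest.approx(0.5)
        assert combined_ripley(3.0, 8.0, 6.0, 16.0, 1.0) == pytest.approx(0.5)

    def test_slide_attaining_both_maxima_scores_one(self):
        for omega in (0.0, 0.3, 1.0):
            assert combined_ripley(6.0, 16.0, 6.0, 16.0, omega) == pytest.approx(1.0)

    def test_invalid_weight(self):
        with pytest.raises(ValueError):
            combined_ripley(1.0, 1.0, 1.0, 1.0, 1.5)


def _outcomes(groups, surv=None):
    out = {}
    for i, g in enumerate(groups):
        pid = f"p{i}"
        st, ev = (surv[i] if surv else (None, None))
        out[pid] = PatientOutcome(pid, g, st, ev)
    return out


class TestGroupTtest:
    def test_identical_groups_give_zero_statistic(self):
        fpm = {f"p{i}": v for i, v in enumerate([0.1, 0.5, 0.9, 0.1, 0.5, 0.9])}
        out = _outcomes(["a"] * 3 + ["b"] * 3)
        cmp_ = compare_groups_ttest(fpm, out)
        assert cmp_.t_statistic == pytest.approx(0.0)

    def test_zero_variance_both_groups_undefined(self):
        fpm = {f"p{i}": 0.0 for i in range(6)}
        out = _outcomes(["a"] * 3 + ["b"] * 3)
        with pytest.raises(ValueError, match="zero variance"):
            compare_groups_ttest(fpm, out)

    def test_small_group_undefined(self):
        fpm = {"p0": 0.1, "p1": 0.2, "p2": 0.3}
        out = _outcomes(["a", "b", "b"])
        with pytest.raises(ValueError, match=">= 2"):
            compare_groups_ttest(fpm, out)

    def test_bh_adjustment_across_phenotype_scan(self, rng):
        out = _outcomes(["a"] * 10 + ["b"] * 10)
        tables = {}
        for ph in ("g1", "g2", "g3"):
            shift = 0.5 if ph == "g1" else 0.0
            tables[ph] = {
                f"p{i}": float(rng.normal(shift if i < 10 else 0.0, 0.05))
                for i in range(20)
            }
        df = ttest_across_phenotypes(tables, out)
        assert {"p_raw", "p_bh", "significant_bh"} <= set(df.columns)
        assert (df["p_bh"] >= df["p_raw"] - 1e-12).all()


class TestSurvivalSplit:
    def test_identical_survival_gives_null_logrank(self):
        fpm = {f"p{i}": (0.9 if i % 2 else 0.1) for i in range(8)}
        surv = [(10.0 * (i // 2 + 1), True) for i in range(8)]
        # same times/events pattern in both FPM halves
        out = _outcomes(["x"] * 8, surv=[(t, e) for t, e in surv])
        sp = survival_mean_split_logrank(fpm, out)
        assert sp.p_value > 0.5

    def test_strong_separation_detected(self, rng):
        fpm, surv, groups = {}, [], []
        for i in range(60):
            hi = i < 30
            fpm[f"p{i}"] = 0.8 if hi else 0.1
            t = rng.exponential(100.0 if hi else 20.0)
            surv.append((float(t), True))
            groups.append("x")
        out = _outcomes(groups, surv)
        sp = survival_mean_split_logrank(fpm, out)
        assert sp.n_high == 30 and sp.n_low == 30
        assert sp.p_value < 0.05

    def test_degenerate_split_undefined(self):
        fpm = {"p0": 1.0, "p1": 0.0, "p2": 0.0, "p3": 0.0}
        out = _outcomes(["x"] * 4, surv=[(10.0, True)] * 4)
        with pytest.raises(ValueError, match="degenerate"):
            survival_mean_split_logrank(fpm, out)


def test_patient_fpm_averages_multiple_slides():
    recs = [
        FpmRecord("s1", "pA", "g", 5, 1.0, 0.1, 0.4),
        FpmRecord("s2", "pA", "g", 5, 1.0, 0.1, 0.6),
        FpmRecord("s3", "pB", "g", 5, 1.0, 0.1, 0.2),
    ]
    fpm = patient_fpm(recs)
    assert fpm == {"pA": pytest.approx(0.5), "pB": pytest.approx(0.2)}
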