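"""Inference machinery: penalized splines, FDR, bootstrap regressions,
GEE, spin test, scale trend."""

import numpy as np
import pandas as pd
import pytest

from pfnets import stats as pst
from pfnets import synthetic as syn
from pfnets.gam import anova_f, fit_gam


@pytest.fixture(scope="module")
def covars():
    rng = np.random.default_rng(1)
    n = 300
    return {
        "n": n,
        "age": rng.uniform(8, 23, n),
        "sex": rng.integers(0, 2, n).astype(float),
        "motion": rng.lognormal(np.log(0.08), 0.4, n),
        "rng": rng,
    }


class TestGam:
    def test_noiseless_linear_recovery(self, covars):
        y = 2.0 * covars["age"]
        fit = fit_gam(y, {"sex": covars["sex"], "motion": covars["motion"]},
                      {"age": covars["age"]})
        assert fit.adj_r2 > 0.999
        assert fit.edf_terms["age"] < 2.0     # shrinks toward the linear limit
        np.testing.assert_allclose(fit.fitted, y, atol=1e-6)

    def test_infinite_penalty_limit_is_linear(self, covars):
        rng = np.random.default_rng(2)
        y = 1.5 * covars["age"] + rng.normal(0, 1.0, covars["n"])
        fit = fit_gam(y, None, {"age": covars["age"]},
                      lambda_bounds=(24.0, 26.0))   # effectively lambda -> inf
        # fitted curve is a straight line in age
        grid = np.linspace(9, 22, 50)
        vals = fit.smooth_values("age", grid)
        resid = vals - np.polyval(np.polyfit(grid, vals, 1), grid)
        assert np.abs(resid).max() < 1e-4

    def test_nonlinear_signal_detected(self, covars):
        rng = np.random.default_rng(3)
        f = 1 / (1 + np.exp(-(covars["age"] - 15)))
        y = f + rng.normal(0, 0.2, covars["n"])
        full = fit_gam(y, None, {"age": covars["age"]})
        red = fit_gam(y, None, {})
        assert full.edf_terms["age"] > 2.0
        assert anova_f(full, red) < 1e-6

    def test_null_effect_calibration(self, covars):
        deltas, ps = [], []
        cov = {"sex": covars["sex"], "motion": covars["motion"]}
        for s in range(60):
            y = np.random.default_rng(500 + s).normal(0, 1, covars["n"])
            full = fit_gam(y, cov, {"age": covars["age"]})
            red = fit_gam(y, cov, {})
            deltas.append(full.adj_r2 - red.adj_r2)
            ps.append(anova_f(full, red))
        assert np.mean(np.abs(deltas)) < 0.01
        # p approximately uniform (mildly liberal is tolerated)
        assert 0.3 < np.mean(ps) < 0.65
        assert np.mean(np.array(ps) < 0.05) <= 0.15

    def test_rank_deficiency_names_columns(self, covars):
        dup = covars["sex"].copy()
        with pytest.raises(ValueError, match="collinear"):
            fit_gam(covars["age"], {"sex": covars["sex"], "sex2": dup},
                    {"age": covars["age"]})


class TestEffectSize:
    def test_identical_fits_zero_delta(self, covars):
        y = np.random.default_rng(0).normal(0, 1, covars["n"])
        fit = fit_gam(y, None, {"age": covars["age"]})
        d, _ = pst.effect_and_significance(fit, fit, linear_sign=1.0)
        assert d == 0.0

    def test_sign_rule(self, covars):
        rng = np.random.default_rng(4)
        y = -0.1 * covars["age"] + rng.normal(0, 0.3, covars["n"])
        d, p, _ = pst.age_effect(y, covars["age"], covars["sex"],
                                 covars["motion"])
        assert d < 0
        assert p < 1e-6

    def test_delta_equals_adjusted_r2_difference(self, covars):
        rng = np.random.default_rng(5)
        y = 0.05 * covars["age"] + rng.normal(0, 0.5, covars["n"])
        cov = {"sex": covars["sex"], "motion": covars["motion"]}
        full = fit_gam(y, cov, {"age": covars["age"]})
        red = fit_gam(y, cov, {})
        d, _ = pst.effect_and_significance(full, red, linear_sign=1.0)
        assert d == pytest.approx(full.adj_r2 - red.adj_r2, abs=1e-12)


class TestDerivativeWindows:
    def test_sigmoid_window_covers_steep_region(self, covars):
        rng = np.random.default_rng(6)
        f = 1 / (1 + np.exp(-(covars["age"] - 15)))
        y = f + rng.normal(0, 0.05, covars["n"])
        fit = fit_gam(y, None, {"age": covars["age"]})
        grid = np.linspace(8.5, 22.5, 200)
        wins = pst.derivative_windows(fit, "age", grid, n_sim=500, seed=1)
        pos = [w for w in wins if w[2] == 1]
        assert pos
        lo = min(w[0] for w in pos)
        hi = max(w[1] for w in pos)
        assert lo <= 15 - 0.2 * 15 * 0.0 + 3 and hi >= 15  # covers inflection
        assert lo < 15 < hi

    def test_flat_response_mostly_no_windows(self, covars):
        # pointwise 95% CIs: on null responses only a small fraction of the
        # grid should be flagged on average
        grid = np.linspace(9, 22, 100)
        fractions = []
        for s in range(10):
            y = np.random.default_rng(700 + s).normal(0, 1, covars["n"])
            fit = fit_gam(y, None, {"age": covars["age"]})
            wins = pst.derivative_windows(fit, "age", grid, n_sim=400, seed=s)
            covered = sum(w[1] - w[0] for w in wins)
            fractions.append(covered / (grid[-1] - grid[0]))
        assert np.mean(fractions) < 0.25

    def test_noiseless_linear_full_span(self, covars):
        y = 3.0 * covars["age"]
        fit = fit_gam(y, None, {"age": covars["age"]})
        grid = np.linspace(9, 22, 100)
        wins = pst.derivative_windows(fit, "age", grid, n_sim=300, seed=3)
        assert len(wins) == 1
        assert wins[0][2] == 1
        assert wins[0][0] == grid[0] and wins[0][1] == grid[-1]


class TestFdr:
    def test_step_up_thresholds(self):
        flags = pst.fdr_bh([0.01, 0.02, 0.03, 0.5], q=0.05)
        assert flags.tolist() == [True, True, True, False]

    def test_all_ones_none(self):
        assert not pst.fdr_bh([1.0, 1.0, 1.0]).any()

    def test_single_small_p(self):
        assert pst.fdr_bh([0.04]).tolist() == [True]


class TestHierarchyRegression:
    def test_noiseless_linear_recovery(self):
        h = np.linspace(0, 1, 40)
        eff = 0.3 - 0.5 * h
        out = pst.hierarchy_regression(eff, h, quadratic=True, n_boot=300,
                                       seed=0)
        assert out["slope"] == pytest.approx(-0.5, abs=1e-8)
        lo, hi = out["quadratic_ci"]
        assert lo <= 0 <= hi or abs(out["quadratic"]) < 1e-8

    def test_planted_parabola_detected(self):
        rng = np.random.default_rng(1)
        h = rng.uniform(0, 1, 450)
        eff = 0.1 - 0.8 * (h - 0.5) ** 2 + rng.normal(0, 0.05, 450)
        out = pst.hierarchy_regression(eff, h, quadratic=True, n_boot=500,
                                       seed=2)
        assert out["quadratic_ci"][1] < 0

    def test_bootstrap_ci_coverage(self):
        # ~95% coverage of the true slope over repeated simulations
        hits = 0
        n_sims = 100
        for s in range(n_sims):
            rng = np.random.default_rng(2000 + s)
            h = rng.uniform(0, 1, 60)
            eff = 0.2 - 0.4 * h + rng.normal(0, 0.1, 60)
            out = pst.hierarchy_regression(eff, h, n_boot=300, seed=s)
            lo, hi = out["slope_ci"]
            hits += lo <= -0.4 <= hi
        assert 0.85 <= hits / n_sims <= 1.0


class TestDistanceRegression:
    def test_pure_distance_signal_partial_equals_full(self):
        rng = np.random.default_rng(3)
        d = rng.uniform(0, 1, 100)
        e = rng.uniform(0, 2, 100)
        y = 0.2 - 0.6 * d
        out = pst.distance_regression(y, d, e, n_boot=200, seed=0)
        assert abs(abs(out["partial_r"]) - abs(out["pearson_r"])) < 0.05

    def test_euclidean_confound_removed(self):
        rng = np.random.default_rng(4)
        e = rng.uniform(0, 2, 200)
        d = 0.4 * e + rng.normal(0, 0.1, 200)   # distance tracks geometry
        y = -0.5 * e + rng.normal(0, 0.02, 200)  # effects purely geometric
        out = pst.distance_regression(y, d, e, n_boot=200, seed=1)
        assert abs(out["partial_r"]) < 0.15
        assert abs(out["pearson_r"]) > 0.5

    def test_seed_determinism(self):
        rng = np.random.default_rng(5)
        d = rng.uniform(0, 1, 50)
        y = -d + rng.normal(0, 0.1, 50)
        a = pst.distance_regression(y, d, n_boot=100, seed=7)
        b = pst.distance_regression(y, d, n_boot=100, seed=7)
        assert a["slope_ci"] == b["slope_ci"]


class TestTensorSurface:
    def test_product_interaction_detected(self):
        rng = np.random.default_rng(6)
        a = rng.uniform(0, 1, 150)
        b = rng.uniform(0, 1, 150)
        y = a * b
        out = pst.tensor_surface(y, a, b, n_boot=300, seed=0)
        assert out["interaction_ci"][0] > 0

    def test_additive_signal_no_interaction(self):
        hits = 0
        for s in range(10):
            rng = np.random.default_rng(100 + s)
            a = rng.uniform(0, 1, 150)
            b = rng.uniform(0, 1, 150)
            y = 0.5 * a - 0.3 * b + rng.normal(0, 0.05, 150)
            out = pst.tensor_surface(y, a, b, n_boot=300, seed=s)
            lo, hi = out["interaction_ci"]
            hits += lo <= 0 <= hi
        assert hits >= 9

    def test_surface_symmetric_under_symmetrized_input(self):
        rng = np.random.default_rng(7)
        a = rng.uniform(0, 1, 100)
        b = rng.uniform(0, 1, 100)
        y = a * b + rng.normal(0, 0.02, 100)
        aa = np.concatenate([a, b])
        bb = np.concatenate([b, a])
        yy = np.concatenate([y, y])
        out = pst.tensor_surface(yy, aa, bb, n_boot=50, seed=0)
        S = out["surface"]
        np.testing.assert_allclose(S, S.T, atol=0.05)


def _gee_long(seed, n=100, scales=range(2, 9), scale_effect=0.0, icc_sd=0.5):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        u = rng.normal(0, icc_sd)
        sex, mot = rng.integers(0, 2), rng.lognormal(np.log(0.08), 0.4)
        age = rng.uniform(8, 23)
        for K in scales:
            rows.append((f"s{i}", K, sex, mot, age,
                         u + scale_effect * K + rng.normal(0, 0.5)))
    return pd.DataFrame(rows, columns=["subject_id", "scale", "sex", "motion",
                                       "age", "coupling"])


class TestGee:
    def test_planted_scale_effect_power(self):
        ps = [pst.gee_scale_test(_gee_long(s, scale_effect=0.05)).wald_p
              for s in range(20)]
        assert np.mean(np.array(ps) < 0.05) >= 0.8

    def test_exchangeable_parameter_recovered(self):
        # planted ICC = 0.5^2 / (0.5^2 + 0.5^2) = 0.5
        fits = [pst.gee_scale_test(_gee_long(100 + s)) for s in range(5)]
        est = np.mean([f.dep_params for f in fits])
        assert abs(est - 0.5) < 0.1

    def test_single_observation_per_cluster_warns(self):
        long = _gee_long(0, n=60, scales=[4])
        X = np.column_stack([np.ones(len(long)), long["scale"]])
        with pytest.warns(UserWarning, match="single observation"):
            pst.fit_gee(long["coupling"].to_numpy(), X,
                        long["subject_id"].to_numpy(), [1])

    def test_interaction_block_detects_planted_modulation(self):
        rng = np.random.default_rng(9)
        rows = []
        for i in range(150):
            u = rng.normal(0, 0.3)
            age = rng.uniform(8, 23)
            sex, mot = rng.integers(0, 2), rng.lognormal(np.log(0.08), 0.4)
            for K in range(2, 9):
                y = u + 0.01 * K * (age - 15.5) + rng.normal(0, 0.3)
                rows.append((f"s{i}", K, sex, mot, age, y))
        long = pd.DataFrame(rows, columns=["subject_id", "scale", "sex",
                                           "motion", "age", "coupling"])
        fit = pst.gee_scale_test(long, interaction_with="age")
        assert fit.wald_p < 0.01


class TestSpin:
    def test_self_correlation(self, mesh2, hierarchy2):
        res = pst.spin_test(hierarchy2, hierarchy2, mesh2, n_rot=99, seed=0)
        assert res.observed == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 100)

    def test_determinism(self, mesh2, hierarchy2):
        other = syn.make_hierarchy_map(mesh2, seed=9)
        a = pst.spin_test(hierarchy2, other, mesh2, n_rot=50, seed=3)
        b = pst.spin_test(hierarchy2, other, mesh2, n_rot=50, seed=3)
        np.testing.assert_array_equal(a.nulls, b.nulls)

    def test_smooth_null_wider_than_shuffle_null(self, mesh2, hierarchy2):
        # spatial autocorrelation inflates the null spread relative to
        # i.i.d. shuffling, which is why the spin test is conservative
        rng = np.random.default_rng(11)
        other = syn.make_hierarchy_map(mesh2, seed=12)
        res = pst.spin_test(hierarchy2, other, mesh2, n_rot=300, seed=4)
        shuffle_nulls = [np.corrcoef(rng.permutation(hierarchy2), other)[0, 1]
                         for _ in range(300)]
        assert res.nulls.std() > 1.5 * np.std(shuffle_nulls)


class TestScaleTrend:
    def test_monotone_stat_gives_unit_correlation(self):
        out = pst.scale_trend([2, 3, 4, 5], [0.1, 0.2, 0.25, 0.4])
        assert out["r"] == pytest.approx(
            np.corrcoef([2, 3, 4, 5], [0.1, 0.2, 0.25, 0.4])[0, 1])
        strict = pst.scale_trend([2, 3, 4], [1.0, 2.0, 3.0])
        assert strict["r"] == pytest.approx(1.0)

    def test_constant_stat_flagged_zero(self):
        out = pst.scale_trend([2, 3, 4], [0.5, 0.5, 0.5])
        assert out["r"] == 0.0
        assert out["degenerate"]

    def test_subject_bootstrap_ci_covers_planted_trend(self):
        # per-scale stat = mean over subjects of subject-level stats with a
        # planted linear trend in scale
        rng = np.random.default_rng(13)
        scales = np.arange(2, 9)
        data = 0.05 * scales[None, :] + rng.normal(0, 0.05, (80, 7))

        def stat_fn(idx):
            return data[idx].mean(axis=0)

        out = pst.scale_trend(scales, data.mean(axis=0), n_boot=300, seed=1,
                              stat_fn=stat_fn, n_subjects=80)
        lo, hi = out["ci"]
        assert lo <= out["r"] <= hi
        assert lo > 0.5  # strong planted trend detected
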