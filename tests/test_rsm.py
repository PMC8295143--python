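"""Response-surface fitting, ANOVA behaviour and desirability optimization."""

import itertools

import numpy as np
import pytest

import ireplan as ip
from ireplan.oracles import SyntheticResponseSpec, generate_synthetic_responses
from ireplan.rsm import (
    larger_is_better,
    optimize_desirability,
    smaller_is_better,
    target_at_limit,
    _composite,
)

# term order: intercept, 5 linear, 4 square (3-level factors)
TRUE_BETA = np.array([50.0, 4.0, -3.0, 8.0, 1.5, -2.0, 1.0, -4.0, 2.5, 0.5])


class TestFit:
    def test_zero_noise_recovers_coefficients(self, l18):
        y = generate_synthetic_responses(SyntheticResponseSpec(TRUE_BETA), l18)
        model = ip.fit_rsm(l18, y)
        np.testing.assert_allclose(model.params_.to_numpy(), TRUE_BETA, atol=1e-8)

    def test_predictions_reproduce_fit_at_design_points(self, l18, table5):
        y = table5["max_temperature_C"].to_numpy()
        model = ip.fit_rsm(l18, y)
        pred = model.predict(l18.natural.to_numpy())
        np.testing.assert_allclose(pred, model.result_.fittedvalues, atol=1e-10)

    def test_too_few_rows_rejected(self, l18, factors):
        small = ip.DesignTable(factors=factors, natural=l18.natural.iloc[:5])
        with pytest.raises(ValueError):
            ip.fit_rsm(small, np.zeros(small.n_runs))

    def test_interaction_pruning_keeps_full_rank(self, l18, table5):
        y = table5["ablation_area_mm2"].to_numpy()
        model = ip.fit_rsm(l18, y, include_interactions=True)
        X = model.result_.model.exog
        assert np.linalg.matrix_rank(X) == X.shape[1] <= 18

    def test_monte_carlo_sd_matches_ols_theory(self, l18):
        # empirical coefficient spread across noisy replicates vs the
        # closed-form OLS covariance
        sd = 5.0
        X = None
        draws = []
        for rep in range(200):
            y = generate_synthetic_responses(
                SyntheticResponseSpec(TRUE_BETA, noise_sd=sd, seed=rep), l18
            )
            model = ip.fit_rsm(l18, y)
            draws.append(model.params_.to_numpy())
            X = model.result_.model.exog
        draws = np.asarray(draws)
        bias = draws.mean(axis=0) - TRUE_BETA
        theory_sd = np.sqrt(np.diag(sd**2 * np.linalg.inv(X.T @ X)))
        assert np.all(np.abs(bias) < 3.5 * theory_sd / np.sqrt(200))
        np.testing.assert_allclose(draws.std(axis=0, ddof=1), theory_sd, rtol=0.2)


class TestAnova:
    def test_null_factor_rarely_significant_under_permutation(self, l18):
        # pulse width has a zero coefficient here, so permuting responses
        # (or not) should leave it non-significant almost always
        beta = TRUE_BETA.copy()
        beta[5] = 0.0  # pulse_width linear
        beta[9] = 0.0  # pulse_width square
        rng = np.random.default_rng(42)
        hits = 0
        n_perm = 100
        y0 = generate_synthetic_responses(SyntheticResponseSpec(beta, noise_sd=3.0, seed=7), l18)
        for _ in range(n_perm):
            y = rng.permutation(y0)
            p = ip.fit_rsm(l18, y).anova().loc["pulse_width_us", "p_value"]
            hits += p > 0.05
        assert hits >= 0.9 * n_perm


class TestDesirability:
    def test_shapes_are_clipped_to_unit_interval(self):
        d = larger_is_better(0.0, 10.0)
        assert d(-5.0) == 0.0 and d(15.0) == 1.0 and d(5.0) == 0.5
        s = smaller_is_better(0.0, 10.0)
        assert s(-5.0) == 1.0 and s(15.0) == 0.0
        t = target_at_limit(37.0, 50.0)
        assert t(37.0) == 0.0
        assert t(50.0) == 1.0
        assert t(50.0001) == 0.0
        assert t(43.5) == pytest.approx(0.5)

    def test_monotone_area_model_pushes_voltage_to_bound(self, l18, factors):
        y = generate_synthetic_responses(
            SyntheticResponseSpec(np.array([100.0, 0, 0, 50.0, 0, 0, 0, 0, 0, 0])), l18
        )
        model = ip.fit_rsm(l18, y)
        res = optimize_desirability(
            {"area": model},
            {"area": larger_is_better(float(y.min()), float(y.max()))},
            factors,
            n_starts=8,
            seed=0,
        )
        assert res.natural["voltage_V"] == pytest.approx(3000.0, abs=1e-3)

    def test_feasible_corner_found_when_limit_binds_almost_everywhere(self, l18, factors):
        # temperature exceeds the 50 C limit except near one corner; the
        # optimizer must find that corner (checked against brute force)
        t_beta = np.array([56.0, 1.0, 1.5, 1.5, 1.5, 1.5, 0, 0, 0, 0])
        a_beta = np.array([100.0, 5.0, 0, 20.0, 0, 0, 0, 0, 0, 0])
        yt = generate_synthetic_responses(SyntheticResponseSpec(t_beta), l18)
        ya = generate_synthetic_responses(SyntheticResponseSpec(a_beta), l18)
        models = {"temp": ip.fit_rsm(l18, yt), "area": ip.fit_rsm(l18, ya)}
        des = {
            "temp": target_at_limit(37.0, 50.0),
            "area": larger_is_better(0.0, 150.0),
        }
        res = optimize_desirability(models, des, factors, n_starts=16, seed=1)
        # brute force over a dense grid
        g = np.linspace(-1, 1, 21)
        pts = np.array(list(itertools.product((-1.0, 1.0), g, g, g, g)))
        d = _composite(pts, models, des)
        assert res.desirability >= d.max() - 1e-3
        assert res.coded[0] == -1.0  # feasibility forces the low corner

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_optimizer_reaches_brute_force_grid_maximum(self, l18, factors, seed):
        rng = np.random.default_rng(seed)
        b1 = rng.normal(0, 3, size=10) + np.array([50] + [0] * 9)
        b2 = rng.normal(0, 2, size=10) + np.array([44] + [0] * 9)
        y1 = generate_synthetic_responses(SyntheticResponseSpec(b1), l18)
        y2 = generate_synthetic_responses(SyntheticResponseSpec(b2), l18)
        models = {"a": ip.fit_rsm(l18, y1), "t": ip.fit_rsm(l18, y2)}
        des = {
            "a": larger_is_better(float(y1.min()), float(y1.max())),
            "t": target_at_limit(37.0, 50.0),
        }
        try:
            res = optimize_desirability(models, des, factors, n_starts=8, seed=seed)
        except RuntimeError:
            pytest.skip("desirability identically zero for this draw")
        g = np.linspace(-1, 1, 21)
        pts = np.array(list(itertools.product((-1.0, 1.0), g, g, g, g)))
        d = _composite(pts, models, des)
        assert res.desirability >= d.max() - 1e-3

    def test_deterministic_given_seed(self, l18, factors):
        y = generate_synthetic_responses(SyntheticResponseSpec(TRUE_BETA, 2.0, 3), l18)
        model = ip.fit_rsm(l18, y)
        des = {"y": larger_is_better(float(y.min()), float(y.max()))}
        r1 = optimize_desirability({"y": model}, des, factors, n_starts=8, seed=5)
        r2 = optimize_desirability({"y": model}, des, factors, n_starts=8, seed=5)
        np.testing.assert_array_equal(r1.coded, r2.coded)

    def test_missing_model_rejected(self, l18, factors):
        y = generate_synthetic_responses(SyntheticResponseSpec(TRUE_BETA), l18)
        model = ip.fit_rsm(l18, y)
        with pytest.raises(ValueError):
            optimize_desirability(
                {"y": model}, {"other": larger_is_better(0, 1)}, factors
            )
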