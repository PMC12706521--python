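"""Predictor screening, Moran's I, spatial weights, OLS/SAR fits, AIC ranking."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import phylogrid as pg
from phylogrid.errors import (
    InvalidInputError,
    InvalidParameterError,
    UndefinedMetricError,
)
from phylogrid.grid import GridSpec
from phylogrid.spatialstats import (
    _sar_concentrated,
    build_weights,
    correlogram,
    fit_ols,
    fit_sar,
    model_select,
    morans_i,
    screen_predictors,
)
from phylogrid.synthio import simulate_sar_response


@pytest.fixture
def grid_weights():
    grid = GridSpec(10, 10, 10.0)
    return grid, build_weights(grid.cell_centers(), 11.0)


class TestScreenPredictors:
    def test_orthogonal_all_retained(self, rng):
        X = pd.DataFrame(rng.normal(size=(200, 4)), columns=list("abcd"))
        X = pd.DataFrame(np.linalg.qr(X.to_numpy())[0], columns=list("abcd"))
        kept, dropped, corr = screen_predictors(X)
        assert kept == list("abcd") and dropped == []

    def test_duplicate_column_dropped_once(self, rng):
        a = rng.normal(size=300)
        X = pd.DataFrame({"a": a, "dup": a, "b": rng.normal(size=300)})
        kept, dropped, _ = screen_predictors(X)
        assert len(dropped) == 1 and dropped[0] in ("a", "dup")
        assert "b" in kept

    def test_hub_removed_by_greedy_rule(self, rng):
        # a and b correlated ~0.9; c nearly independent: the member of the
        # violating pair with the larger mean |r| is dropped — matches
        # enumeration over removal orders, which must end with all |r| < 0.5
        n = 2000
        a = rng.normal(size=n)
        b = 0.9 * a + np.sqrt(1 - 0.81) * rng.normal(size=n)
        c = 0.1 * a + np.sqrt(1 - 0.01) * rng.normal(size=n)
        X = pd.DataFrame({"a": a, "b": b, "c": c})
        kept, dropped, corr = screen_predictors(X)
        abs_corr = X.corr().abs()
        np.fill_diagonal(abs_corr.values, 0)
        involved = abs_corr.index[(abs_corr >= 0.5).any(axis=0)]
        hub = abs_corr.mean(axis=0).loc[involved].idxmax()
        assert dropped == [hub]
        assert set(kept) == {"a", "b", "c"} - {hub}
        sub = X[kept].corr().abs().to_numpy()
        np.fill_diagonal(sub, 0)
        assert sub.max() < 0.5

    def test_zero_variance_dropped_with_warning(self, rng):
        X = pd.DataFrame({"flat": np.ones(50), "a": rng.normal(size=50),
                          "b": rng.normal(size=50)})
        kept, dropped, _ = screen_predictors(X)
        assert "flat" in dropped


class TestMoransI:
    def test_hand_example_matches_formula(self):
        x = np.array([1.0, 3.0, 2.0])
        W = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        res = morans_i(x, W)
        z = x - x.mean()
        expected = (3 / W.sum()) * (z @ W @ z) / (z @ z)
        assert res["I"] == pytest.approx(expected, abs=1e-12)
        assert res["expected"] == pytest.approx(-0.5)

    def test_null_calibration(self, grid_weights, rng):
        grid, W = grid_weights
        vals = [morans_i(rng.normal(size=100), W)["I"] for _ in range(1000)]
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - (-1 / 99)) < 3 * se

    def test_alternating_pattern_near_negative_bound(self):
        # checkerboard on a 4x4 rook torus: strongest negative autocorrelation
        grid = GridSpec(4, 4, 1.0)
        x = np.array([(r + c) % 2 for r in range(4) for c in range(4)], dtype=float)
        n = 16
        W = np.zeros((n, n))
        for r in range(4):
            for c in range(4):
                i = r * 4 + c
                for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    W[i, ((r + dr) % 4) * 4 + (c + dc) % 4] = 1
        res = morans_i(x, W)
        assert res["I"] == pytest.approx(-1.0, abs=1e-12)

    def test_affine_invariance(self, grid_weights, rng):
        grid, W = grid_weights
        x = rng.normal(size=100)
        assert morans_i(3.2 * x + 7, W)["I"] == pytest.approx(morans_i(x, W)["I"], abs=1e-12)

    def test_constant_x_rejected(self, grid_weights):
        grid, W = grid_weights
        with pytest.raises(UndefinedMetricError):
            morans_i(np.ones(100), W)


class TestBuildWeights:
    def test_rook_neighbors_on_regular_grid(self):
        grid = GridSpec(5, 5, 10.0)
        W = build_weights(grid.cell_centers(), 10.5, style="binary")
        deg = np.asarray(W.matrix().sum(axis=1)).ravel()
        # corner 2, edge 3, interior 4 neighbors
        assert sorted(np.unique(deg)) == [2, 3, 4]
        assert deg[grid.cell_id(2, 2)] == 4

    def test_row_standardized_rows_sum_to_one(self, grid_weights):
        _, W = grid_weights
        rows = np.asarray(W.matrix().sum(axis=1)).ravel()
        assert np.allclose(rows, 1.0)

    def test_large_band_gives_complete_graph(self):
        coords = np.array([[0, 0], [1, 0], [0, 1], [5, 5]], dtype=float)
        W = build_weights(coords, 100.0, style="binary")
        assert W.matrix().nnz == 12  # n(n-1)

    def test_all_isolated_rejected(self):
        with pytest.raises(InvalidInputError):
            build_weights(np.array([[0.0, 0.0], [50.0, 50.0]]), 1.0)


class TestOls:
    def test_exact_data_recovered(self, rng):
        X = rng.normal(size=(50, 3))
        beta = np.array([2.0, 0.5, -1.0, 3.0])
        y = beta[0] + X @ beta[1:]
        fit = fit_ols(y, X)
        assert np.allclose(fit.beta, beta, atol=1e-10)
        assert np.allclose(fit.residuals, 0, atol=1e-10)

    def test_intercept_only_is_mean(self, rng):
        y = rng.normal(size=40)
        fit = fit_ols(y, np.empty((40, 0)))
        assert fit.beta[0] == pytest.approx(y.mean(), abs=1e-12)

    def test_matches_statsmodels_oracle(self, rng):
        X = rng.normal(size=(80, 2))
        y = 1 + X @ np.array([0.7, -0.3]) + rng.normal(size=80)
        fit = fit_ols(y, X)
        ref = sm.OLS(y, sm.add_constant(X)).fit()
        assert np.allclose(fit.beta, ref.params, atol=1e-10)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-8)

    def test_rank_deficiency_names_columns(self, rng):
        a = rng.normal(size=30)
        X = pd.DataFrame({"a": a, "twice_a": 2 * a})
        with pytest.raises(InvalidInputError, match="twice_a"):
            fit_ols(rng.normal(size=30), X)


class TestSar:
    def setup_method(self):
        self.grid = GridSpec(20, 20, 10.0)
        self.W = build_weights(self.grid.cell_centers(), 11.0)
        rng = np.random.default_rng(123)
        self.X = rng.normal(size=(400, 2))
        self.beta = np.array([1.0, 2.0, -1.5])  # incl. intercept

    def _simulate(self, lam, seed):
        Xd = np.column_stack([np.ones(400), self.X])
        return simulate_sar_response(Xd, self.W, self.beta, lam=lam, sigma=1.0, seed=seed)

    def test_reduces_to_ols_at_lambda_zero(self):
        y = self._simulate(0.5, seed=0)
        ols = fit_ols(y, self.X)
        eigs = self.W.eigenvalues()
        Xd = np.column_stack([np.ones(400), self.X])
        for model in ("error", "lag"):
            pieces = _sar_concentrated(y, Xd, self.W.matrix(), eigs, model)
            ll0, beta0, _, _ = pieces(0.0)
            assert ll0 == pytest.approx(ols.loglik, abs=1e-8)
            assert np.allclose(beta0, ols.beta, atol=1e-8)

    def test_logdet_dual_route(self):
        eigs = self.W.eigenvalues()
        Wd = self.W.dense()
        for lam in (-0.4, 0.0, 0.6, 0.9):
            direct = np.linalg.slogdet(np.eye(400) - lam * Wd)[1]
            assert np.log(1 - lam * eigs).sum() == pytest.approx(direct, abs=1e-8)

    def test_lambda_and_beta_recovered(self):
        lams, betas = [], []
        for seed in range(15):
            y = self._simulate(0.7, seed)
            fit = fit_sar(y, self.X, self.W, "error")
            lams.append(fit.spatial_param)
            betas.append(fit.beta)
        assert abs(np.mean(lams) - 0.7) < 0.1
        assert np.allclose(np.mean(betas, axis=0), self.beta, atol=0.1)

    def test_likelihood_no_worse_than_ols_on_sar_data(self):
        for seed in range(5):
            y = self._simulate(0.7, seed)
            fit = fit_sar(y, self.X, self.W, "error")
            ols = fit_ols(y, self.X)
            assert fit.loglik >= ols.loglik - 1e-8


class TestModelSelect:
    def setup_method(self):
        grid = GridSpec(10, 10, 10.0)
        self.W = build_weights(grid.cell_centers(), 11.0)
        rng = np.random.default_rng(9)
        self.X = rng.normal(size=(100, 2))

    def test_duplicate_fits_tie_break_by_parameters(self, rng):
        y = rng.normal(size=100)
        f1 = fit_ols(y, self.X)
        f2 = fit_ols(y, self.X)
        table = model_select([f1, f2])
        assert table["delta_aic"].iloc[1] == 0.0

    def test_mixed_responses_rejected(self, rng):
        y = rng.normal(size=100)
        f1 = fit_ols(y, self.X, response="PD")
        f2 = fit_ols(y, self.X, response="SR")
        with pytest.raises(InvalidInputError):
            model_select([f1, f2])

    def test_sar_wins_on_autocorrelated_data(self):
        wins = 0
        for seed in range(10):
            Xd = np.column_stack([np.ones(100), self.X])
            y = simulate_sar_response(Xd, self.W, np.array([1, 0.5, -0.5]),
                                      lam=0.7, sigma=1.0, seed=seed)
            table = model_select([fit_ols(y, self.X), fit_sar(y, self.X, self.W, "error")])
            wins += table["model"].iloc[0] == "sar_error"
        assert wins >= 9

    def test_ols_parsimonious_under_the_null(self):
        close = 0
        for seed in range(10):
            Xd = np.column_stack([np.ones(100), self.X])
            y = simulate_sar_response(Xd, self.W, np.array([1, 0.5, -0.5]),
                                      lam=0.0, sigma=1.0, seed=seed)
            table = model_select([fit_ols(y, self.X), fit_sar(y, self.X, self.W, "error")])
            ols_row = table[table["model"] == "ols"].iloc[0]
            close += ols_row["delta_aic"] <= 4.0
        assert close >= 7


class TestCorrelogram:
    def test_deterministic(self, rng):
        grid = GridSpec(8, 8, 10.0)
        x = rng.normal(size=64)
        a = correlogram(x, grid.cell_centers(), n_classes=5)
        b = correlogram(x, grid.cell_centers(), n_classes=5)
        assert a.equals(b)

    def test_sar_data_first_class_significant(self):
        grid = GridSpec(15, 15, 10.0)
        W = build_weights(grid.cell_centers(), 11.0)
        hits = 0
        for seed in range(10):
            y = simulate_sar_response(np.ones((225, 1)), W, np.array([0.0]),
                                      lam=0.7, sigma=1.0, seed=seed)
            cg = correlogram(y, grid.cell_centers(), n_classes=6)
            hits += cg["p"].iloc[0] < 0.05 and cg["I"].iloc[0] > 0
        assert hits >= 9

    def test_iid_false_positive_rate_near_alpha(self, rng):
        grid = GridSpec(8, 8, 10.0)
        sig = []
        for _ in range(40):
            cg = correlogram(rng.normal(size=64), grid.cell_centers(), n_classes=5)
            sig.extend((cg["p"] < 0.05).tolist())
        rate = np.mean(sig)
        se = np.sqrt(0.05 * 0.95 / len(sig))
        assert rate < 0.05 + 3 * se


class TestSignRecovery:
    def test_environmental_wiring_signs_recovered(self):
        # diversity wired positively to precipitation and ruggedness and
        # negatively to climate velocity, with SAR errors
        grid = GridSpec(12, 12, 25.0)
        W = build_weights(grid.cell_centers(), 26.0)
        rng = np.random.default_rng(7)
        n = grid.n_cells
        env = pd.DataFrame({
            "precip": rng.normal(size=n),
            "ruggedness": rng.normal(size=n),
            "velocity": rng.normal(size=n),
        })
        beta = np.array([10.0, 1.0, 0.8, -1.2])
        Xd = np.column_stack([np.ones(n), env.to_numpy()])
        ok = 0
        n_seeds = 20
        for seed in range(n_seeds):
            y = simulate_sar_response(Xd, W, beta, lam=0.5, sigma=1.0, seed=seed)
            fit = fit_sar(y, env, W, "error")
            signs = np.sign(fit.beta[1:])
            ok += np.array_equal(signs, [1, 1, -1])
        assert ok >= int(0.95 * n_seeds)
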