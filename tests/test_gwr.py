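"""GWR/MGWR against weighted-least-squares, OLS-limit and search oracles."""

import math

import numpy as np
import pytest

import divgrid as dg
from divgrid.errors import (
    DegenerateDesignError,
    InsufficientDataError,
    InvalidConfigError,
)
from divgrid.gwr import (
    GWR,
    MGWR,
    aicc,
    classify_residuals,
    golden_section_minimize,
    run_model_suite,
)


def make_data(seed=0, n=25, spatial=True):
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0, 100, (n, 2))
    x = rng.normal(size=n)
    beta = 0.5 + (coords[:, 0] / 100 if spatial else 0.0)
    y = 1.0 + beta * x + rng.normal(0, 0.3, n)
    return y, x, coords


def wls_oracle(y, x, coords, bandwidth):
    """Per-location weighted normal equations, solved independently."""
    n = len(y)
    X = np.column_stack([np.ones(n), x])
    params = np.zeros((n, 2))
    hat = np.zeros(n)
    for i in range(n):
        d2 = np.sum((coords - coords[i]) ** 2, axis=1)
        w = np.exp(-0.5 * d2 / bandwidth**2)
        A = X.T @ (w[:, None] * X)
        b = X.T @ (w * y)
        beta = np.linalg.solve(A, b)
        params[i] = beta
        hat[i] = w[i] * (X[i] @ np.linalg.solve(A, X[i]))
    return params, hat


class TestGWRFit:
    def test_exact_linear_data_recovered_everywhere(self):
        rng = np.random.default_rng(1)
        coords = rng.uniform(0, 10, (15, 2))
        x = rng.normal(size=15)
        y = 2.0 - 3.0 * x
        res = GWR(y, x, coords).fit(bandwidth=4.0)
        np.testing.assert_allclose(res.params[:, 0], 2.0, atol=1e-8)
        np.testing.assert_allclose(res.params[:, 1], -3.0, atol=1e-8)
        np.testing.assert_allclose(res.resid, 0.0, atol=1e-8)
        np.testing.assert_allclose(res.local_r2, 1.0, atol=1e-8)

    @pytest.mark.parametrize("seed,bandwidth", [(0, 8.0), (1, 20.0),
                                                (2, 55.0)])
    def test_matches_bruteforce_wls_oracle(self, seed, bandwidth):
        y, x, coords = make_data(seed)
        res = GWR(y, x, coords).fit(bandwidth=bandwidth)
        params, hat = wls_oracle(y, x, coords, bandwidth)
        np.testing.assert_allclose(res.params, params, atol=1e-8)
        assert res.tr_S == pytest.approx(hat.sum(), abs=1e-8)

    def test_huge_bandwidth_reduces_to_ols(self):
        y, x, coords = make_data(3)
        extent = float(np.ptp(coords))
        res = GWR(y, x, coords).fit(bandwidth=1e6 * extent)
        beta = np.linalg.lstsq(np.column_stack([np.ones_like(x), x]), y,
                               rcond=None)[0]
        np.testing.assert_allclose(res.params, np.tile(beta, (len(y), 1)),
                                   atol=1e-6)
        # local R2 becomes spatially constant and equals the OLS R2
        ols_r2 = 1 - np.sum((y - beta[0] - beta[1] * x) ** 2) \
            / np.sum((y - y.mean()) ** 2)
        np.testing.assert_allclose(res.local_r2, ols_r2, atol=1e-6)

    def test_residual_identity_and_r2_bounds(self):
        y, x, coords = make_data(4)
        res = GWR(y, x, coords).fit(bandwidth=15.0)
        np.testing.assert_array_equal(res.resid, y - res.fittedvalues)
        assert np.all((res.local_r2 >= 0) & (res.local_r2 <= 1))

    def test_constant_x_flags_degeneracy_without_crash(self):
        rng = np.random.default_rng(5)
        coords = rng.uniform(0, 10, (12, 2))
        y = rng.normal(size=12)
        res = GWR(y, np.ones(12), coords).fit(bandwidth=5.0)
        assert res.degenerate.all()
        assert np.all(res.params[:, 1] == 0)

    def test_too_few_locations_raise(self):
        with pytest.raises(InsufficientDataError):
            GWR([1, 2], [1, 2], [[0, 0], [1, 1]])


class TestAICc:
    def test_formula_against_independent_evaluation(self):
        y, x, coords = make_data(6, n=20)
        res = GWR(y, x, coords).fit(bandwidth=12.0)
        n, rss, trs = res.nobs, res.rss, res.tr_S
        by_hand = (n * math.log(rss / n) + n * math.log(2 * math.pi)
                   + n * (n + trs) / (n - 2 - trs))
        assert res.aicc == pytest.approx(by_hand, abs=1e-10)

    def test_penalty_strictly_increases_with_trs(self):
        assert aicc(10.0, 30, 8.0) > aicc(10.0, 30, 4.0)

    def test_ols_limit_value(self):
        y, x, coords = make_data(7)
        res = GWR(y, x, coords).fit(bandwidth=1e6 * float(np.ptp(coords)))
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        rss = float(np.sum((y - X @ beta) ** 2))
        assert res.aicc == pytest.approx(aicc(rss, len(y), 2.0), abs=1e-4)

    def test_saturated_fit_rejected(self):
        with pytest.raises(InvalidConfigError):
            aicc(1.0, 10, 9.0)


class TestBandwidthSearch:
    def test_convex_surrogate_minimum(self):
        b, _ = golden_section_minimize(lambda t: (t - 3.0) ** 2, 0.1, 10.0)
        assert b == pytest.approx(3.0, abs=1e-2)

    def test_degenerate_interval_rejected(self):
        with pytest.raises(InvalidConfigError):
            golden_section_minimize(lambda t: t, 2.0, 2.0)

    def test_matches_dense_grid_search(self):
        y, x, coords = make_data(8, n=30)
        model = GWR(y, x, coords)
        lo, hi = model.default_interval()
        b_golden = model.select_bandwidth((lo, hi))
        grid = np.linspace(lo, hi, 200)

        def safe_aicc(b):
            try:
                return model._fit_at(b).aicc
            except InvalidConfigError:
                return np.inf

        scores = [safe_aicc(b) for b in grid]
        b_grid = grid[int(np.argmin(scores))]
        step = grid[1] - grid[0]
        assert model._fit_at(b_golden).aicc <= min(scores) + 1e-6 or \
            abs(b_golden - b_grid) <= step

    def test_search_aicc_matches_refit(self):
        """No stale caching: the reported AICc equals a fresh evaluation."""
        y, x, coords = make_data(9, n=30)
        model = GWR(y, x, coords)
        res = model.fit()
        assert model._fit_at(res.bandwidth).aicc == pytest.approx(res.aicc)


class TestMGWR:
    def test_tied_bandwidths_reproduce_gwr(self):
        y, x, coords = make_data(10, n=30)
        r_gwr = GWR(y, x, coords).fit(bandwidth=18.0)
        r_mgwr = MGWR(y, x, coords).fit(bandwidths=(18.0, 18.0))
        np.testing.assert_allclose(r_mgwr.fittedvalues, r_gwr.fittedvalues,
                                   atol=1e-8)
        np.testing.assert_allclose(r_mgwr.params, r_gwr.params, atol=1e-8)

    def test_zero_variance_predictor_rejected(self):
        rng = np.random.default_rng(11)
        with pytest.raises(DegenerateDesignError):
            MGWR(rng.normal(size=10), np.ones(10),
                 rng.uniform(0, 1, (10, 2)))

    def test_varying_slope_surface_recovered(self):
        """Median correlation between true and estimated slope > 0.8."""
        cors = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 120
            coords = rng.uniform(0, 100, (n, 2))
            x = rng.normal(size=n)
            slope = 1.0 + coords[:, 0] / 50.0
            y = 2.0 + slope * x + rng.normal(0, 0.3, n)
            res = MGWR(y, x, coords).fit()
            cors.append(np.corrcoef(slope, res.params[:, 1])[0, 1])
        assert np.median(cors) > 0.8


class TestModelSuite:
    def test_fits_exactly_the_six_listed_pairs(self):
        from divgrid.pipeline import scenario_analysis
        from divgrid.gwr import MODEL_PAIRS

        res = scenario_analysis("congruent", seed=0, n_species=60,
                                grid_rows=8, grid_cols=8,
                                models=MODEL_PAIRS)
        assert set(res["suite"]) == {
            "FD~TD", "PD~TD", "FD~PD", "WE~FE", "WE~PE", "FE~PE"
        }

    def test_residual_sign_semantics(self):
        labels = classify_residuals(np.array([0.5, -0.5, 0.0]))
        assert list(labels) == ["positive", "negative", "neutral"]
        labels = classify_residuals(np.array([0.05, -0.05]), eps=0.1)
        assert list(labels) == ["neutral", "neutral"]

    def test_insufficient_cells_raise(self):
        from divgrid.surfaces import METRICS, SurfaceSet
        from divgrid.grid import GridSpec, RedundancyReport

        grid = GridSpec(0, 0, 1.0, 2, 2)
        vals = np.full(4, np.nan)
        vals[:2] = [1.0, 2.0]
        ss = SurfaceSet(
            grid=grid, values={m: vals.copy() for m in METRICS},
            redundancy=RedundancyReport(np.full(4, 0.9), 0.9, 4),
            low_redundancy=np.zeros(4, bool),
        )
        with pytest.raises(InsufficientDataError):
            run_model_suite(ss)
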