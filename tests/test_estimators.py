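import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from chmbiomass.calibration import BiomassModel
from chmbiomass.estimators import (
    InsufficientSampleError,
    SaeInputs,
    combine_mb,
    empirical_coverage,
    estimate_db,
    estimate_mb,
    estimate_sae,
    fit_sae_working_model,
    predict_map,
)
from chmbiomass.landscape import LandscapeConfig, generate_landscape
from chmbiomass.metrics import stamp_labels, window_metrics


def simple_model(params, predictors=("h50", "fc"), cov=None):
    params = np.asarray(params, dtype=float)
    k = params.size
    cov = np.zeros((k, k)) if cov is None else np.asarray(cov, dtype=float)
    return BiomassModel(stratum=1, predictors=predictors, params=params, cov=cov)


class TestDesignBased:
    def test_constant_sample(self):
        res = estimate_db(np.array([50.0, 50.0, 50.0]))
        assert res.mean == 50.0
        assert res.se == 0.0
        assert res.rel_se_pct == 0.0

    def test_closed_form_example(self):
        # {10,20,30}: mean 20, s2 = 100, SE = sqrt(100/3), eps = t2 * SE
        res = estimate_db(np.array([10.0, 20.0, 30.0]))
        assert res.mean == pytest.approx(20.0)
        assert res.se == pytest.approx(math.sqrt(100.0 / 3.0))
        t2 = sps.t.ppf(0.975, 2)
        assert t2 == pytest.approx(4.3027, abs=1e-4)
        assert res.epsilon == pytest.approx(t2 * res.se)
        assert res.epsilon == pytest.approx(24.84, abs=0.01)
        assert res.rel_se_pct == pytest.approx(124.2, abs=0.1)
        assert res.ci_low == pytest.approx(res.mean - res.epsilon)
        assert res.ci_high == pytest.approx(res.mean + res.epsilon)

    def test_large_n_t_limit(self):
        rng = np.random.default_rng(0)
        res = estimate_db(rng.normal(100, 10, 5000))
        assert res.epsilon / res.se == pytest.approx(1.96, abs=0.005)

    def test_insufficient_sample(self):
        with pytest.raises(InsufficientSampleError):
            estimate_db(np.array([42.0]))

    def test_monotone_uncertainty_on_nested_subsamples(self):
        # repeating the same pattern keeps dispersion fixed while n grows
        base = np.array([10.0, 20.0, 30.0])
        rels = [
            estimate_db(np.tile(base, k)).rel_se_pct for k in (1, 2, 4, 8, 16)
        ]
        assert all(a > b for a, b in zip(rels, rels[1:]))


class TestModelBased:
    def test_two_cell_one_parameter_example(self):
        # f = a*h with var(a) = v: SE = (1/2)(2+4) sqrt(v) = 3 sqrt(v)
        v = 0.09
        m = simple_model([2.0, 1.0], predictors=("h50",),
                         cov=[[v, 0.0], [0.0, 0.0]])
        res = estimate_mb(np.array([2.0, 4.0]), m)
        assert res.se == pytest.approx(3.0 * math.sqrt(v))
        assert res.mean == pytest.approx(6.0)

    def test_zero_covariance_zero_se(self):
        m = simple_model([0.05, 1.4, 1.2])
        rng = np.random.default_rng(1)
        res = estimate_mb(rng.uniform(2, 20, 100), m, rng.uniform(0.1, 1, 100))
        assert res.se == 0.0

    def test_identical_cells_degenerate_population(self):
        cov = np.diag([1e-4, 1e-3, 1e-3])
        m = simple_model([0.05, 1.4, 1.2], cov=cov)
        h1 = np.full(25, 10.0)
        h2 = np.full(25, 0.8)
        res = estimate_mb(h1, m, h2)
        single = m.predict(np.array([10.0]), np.array([0.8]))[0]
        assert res.mean == pytest.approx(single)
        z = m.gradients(np.array([10.0]), np.array([0.8]))[0]
        assert res.se == pytest.approx(math.sqrt(z @ cov @ z))

    def test_factorized_se_equals_double_sum_oracle(self):
        from chmbiomass.acceptance import mb_se_double_sum_oracle

        rng = np.random.default_rng(3)
        h1 = rng.uniform(2, 30, 50)
        h2 = rng.uniform(0.05, 1.0, 50)
        A = rng.normal(size=(3, 3))
        m = simple_model([0.02, 1.6, 1.1], cov=A @ A.T / 1e4)
        res = estimate_mb(h1, m, h2)
        oracle = mb_se_double_sum_oracle(m.gradients(h1, h2), m.cov)
        assert res.se == pytest.approx(oracle, rel=1e-10)

    def test_zero_height_cells_contribute_zero(self):
        m = simple_model([1.0, 1.0], predictors=("h50",), cov=[[1.0, 0], [0, 0]])
        res = estimate_mb(np.array([0.0, 0.0, 6.0]), m)
        assert res.mean == pytest.approx(2.0)
        assert res.se == pytest.approx(6.0 / 3.0)  # only the 6-m cell's gradient

    def test_combine_mb_weights_by_units(self):
        m = simple_model([1.0, 1.0], predictors=("h50",))
        a = estimate_mb(np.full(10, 4.0), m)
        b = estimate_mb(np.full(30, 8.0), m)
        comb = combine_mb([a, b])
        assert comb.mean == pytest.approx((10 * 4 + 30 * 8) / 40)
        assert comb.N == 40

    def test_mb_unbiased_under_correct_model(self):
        # linear generator link at the 44-m scale with the true parameters
        cfg = LandscapeConfig(
            extent_m=(1100.0, 1100.0), stratum_codes=(1,), mean_height_m=10.0,
            height_cv=0.4, gap_fraction=0.1, agb_coefficient=5.0,
            agb_exponent=1.0, n_domains=1, seed=2,
        )
        land = generate_landscape(cfg)
        mg = window_metrics(land.chm, 44.0)
        m = simple_model([5.0, 1.0], predictors=("h_mean",))
        res = estimate_mb(mg.metric("h_mean").ravel(), m)
        truth = land.truth.true_mean("stratum", 1)
        assert abs(res.mean - truth) / truth < 0.03


class TestPredictMap:
    def _grid(self, h50, fc, stratum_code=1):
        from chmbiomass.raster import RasterGrid

        chm_vals = np.zeros((4, 4))
        mg = window_metrics(RasterGrid((0.0, 0.0), 1.0, chm_vals), 2.0)
        mg.grids["h50"] = mg.grids["h50"].__class__((0.0, 0.0), 2.0, np.asarray(h50, float))
        mg.grids["fc"] = mg.grids["fc"].__class__((0.0, 0.0), 2.0, np.asarray(fc, float))
        lab = RasterGrid(
            (0.0, 0.0), 1.0, np.full((4, 4), stratum_code, dtype=np.int16), nodata=-1
        )
        stamp_labels(mg, lab, lab)
        return mg

    def test_zero_height_predicts_zero(self):
        mg = self._grid(np.zeros((2, 2)), np.full((2, 2), 0.5))
        pred = predict_map(mg, {1: simple_model([1.0, 1.0, 1.0])})
        assert np.all(pred.values == 0.0)

    def test_unit_parameters(self):
        mg = self._grid(np.full((2, 2), 2.0), np.full((2, 2), 0.5))
        pred = predict_map(mg, {1: simple_model([1.0, 1.0, 1.0])})
        assert np.allclose(pred.values, 1.0)

    def test_missing_model_raises(self):
        mg = self._grid(np.ones((2, 2)), np.ones((2, 2)), stratum_code=7)
        with pytest.raises(KeyError, match="7"):
            predict_map(mg, {1: simple_model([1.0, 1.0, 1.0])})


class TestSae:
    def test_zero_residuals(self):
        inp = SaeInputs(
            x_bar=np.array([1.0, 5.0]), beta=np.array([2.0, 3.0]),
            beta_cov=np.eye(2) * 0.01, residuals=np.zeros(8),
        )
        res = estimate_sae(inp)
        assert res.mean == pytest.approx(17.0)
        # third variance term vanishes
        assert res.se == pytest.approx(
            math.sqrt(np.array([1.0, 5.0]) @ (np.eye(2) * 0.01) @ np.array([1.0, 5.0]))
        )

    def test_intercept_only_reduces_to_db_mean(self):
        rng = np.random.default_rng(4)
        y = rng.gamma(3.0, 30.0, 40)
        beta = np.array([y.mean()])
        resid = y - beta[0]
        s2 = resid.var(ddof=1)
        idx = rng.choice(40, 12, replace=False)
        res = estimate_sae(
            SaeInputs(
                x_bar=np.array([1.0]), beta=beta,
                beta_cov=np.array([[s2 / 40]]), residuals=resid[idx],
            )
        )
        assert res.mean == pytest.approx(y[idx].mean(), abs=1e-12)
        local_s2 = resid[idx].var(ddof=1)
        assert res.se == pytest.approx(math.sqrt(s2 / 40 + local_s2 / 12))

    def test_rel_se_monotone_in_n(self):
        spread = np.array([-20.0, -10.0, 0.0, 10.0, 20.0])
        small = estimate_sae(
            SaeInputs(np.array([1.0]), np.array([100.0]), np.zeros((1, 1)), spread)
        )
        large = estimate_sae(
            SaeInputs(np.array([1.0]), np.array([100.0]), np.zeros((1, 1)),
                      np.tile(spread, 8))
        )
        assert small.rel_se_pct > large.rel_se_pct

    def test_zero_plots_synthetic_flagged(self):
        res = estimate_sae(
            SaeInputs(np.array([1.0, 3.0]), np.array([5.0, 2.0]),
                      np.eye(2), np.array([]))
        )
        assert res.mean == pytest.approx(11.0)
        assert res.flag == "no_variance"
        assert math.isnan(res.se)

    def test_single_plot_flagged(self):
        res = estimate_sae(
            SaeInputs(np.array([1.0]), np.array([5.0]), np.eye(1), np.array([2.0]))
        )
        assert res.mean == pytest.approx(7.0)
        assert res.flag == "no_variance"


class TestWorkingModel:
    def _table(self, X, y):
        df = pd.DataFrame(X, columns=["h99", "h_mean", "fc"])
        df["agbd_mg_ha"] = y
        return df

    def test_exact_linear_zero_residuals(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(1, 20, (30, 3))
        y = 4.0 + X @ np.array([2.0, 1.0, 10.0])
        beta, cov, resid = fit_sae_working_model(self._table(X, y))
        assert np.allclose(beta, [4.0, 2.0, 1.0, 10.0])
        assert np.allclose(resid, 0.0, atol=1e-9)

    def test_orthogonal_design_covariance(self):
        # +/-1 design with X'X = n I: coefficient covariance ~ s2/n * I
        rng = np.random.default_rng(6)
        n = 4096
        signs = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]])
        X = np.tile(signs, (n // 4, 1)).astype(float)
        y = rng.normal(0.0, 1.0, n)
        beta, cov, _ = fit_sae_working_model(self._table(X, y))
        assert np.allclose(cov, np.eye(4) * cov[0, 0], atol=cov[0, 0] * 1e-6)
        assert cov[0, 0] == pytest.approx(1.0 / n, rel=0.15)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(7)
        X = rng.uniform(1, 20, (25, 3))
        y = 4.0 + X @ np.array([2.0, 1.0, 10.0]) + rng.normal(0, 5, 25)
        df = self._table(X, y)
        beta1, *_ = fit_sae_working_model(df)
        beta2, *_ = fit_sae_working_model(df.sample(frac=1.0, random_state=1))
        assert np.allclose(beta1, beta2)

    def test_rank_deficient_rejected(self):
        X = np.ones((20, 3))
        X[:, 1] = 2.0
        X[:, 2] = 3.0
        with pytest.raises(ValueError, match="rank"):
            fit_sae_working_model(self._table(X, np.arange(20.0)))


class TestEmpiricalCoverage:
    def test_infinite_ci_covers_always(self):
        cov, _ = empirical_coverage([(-math.inf, math.inf)] * 60, 100.0)
        assert cov == 1.0

    def test_wrong_point_ci_never_covers(self):
        cov, _ = empirical_coverage([(5.0, 5.0)] * 60, 100.0)
        assert cov == 0.0
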