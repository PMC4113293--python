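import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from streambeta import (
    AiccModelSelector,
    aicc,
    model_select,
    ols_fit,
    partial_spearman,
    refit_excluding,
    spearman,
)
from streambeta.data_model import ValidationError
from streambeta.inference import _akaike_weights


class TestOlsFit:
    def test_exact_linear_relationship(self):
        x = np.arange(10.0)
        fit = ols_fit(3.0 + 2.0 * x, x)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.coefficients["x1"] == pytest.approx(2.0, abs=1e-10)
        assert fit.coefficients["intercept"] == pytest.approx(3.0, abs=1e-9)

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.normal(size=(40, 3))
        y = rng.normal(size=40)
        fit = ols_fit(y, x)
        design = np.column_stack([np.ones(40), x])
        beta = np.linalg.solve(design.T @ design, design.T @ y)
        got = [fit.coefficients["intercept"]] + [
            fit.coefficients[f"x{i+1}"] for i in range(3)
        ]
        np.testing.assert_allclose(got, beta, atol=1e-10)

    def test_independent_noise_has_null_slope(self):
        rng = np.random.default_rng(123)
        x = rng.normal(size=1000)
        y = rng.normal(size=1000)
        fit = ols_fit(y, x)
        assert abs(fit.adjusted_r2) < 0.01
        assert fit.slope_p_values["x1"] > 0.01  # CI covers zero

    def test_collinear_design_rejected(self):
        x = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(ValidationError, match="collinear|rank"):
            ols_fit(np.arange(10.0), x)

    def test_adjusted_r2_formula(self, rng):
        x = rng.normal(size=(30, 2))
        y = x @ [1.0, -0.5] + rng.normal(size=30)
        fit = ols_fit(y, x)
        assert fit.adjusted_r2 == pytest.approx(
            1 - (1 - fit.r2) * 29 / (30 - 2 - 1), rel=1e-12
        )


class TestAicc:
    def test_correction_term_arithmetic(self):
        # 2k(k+1)/(n-k-1) with k=3, n=10 -> 24/6 = 4
        assert aicc(0.0, 3, 10) - (2 * 3) == pytest.approx(4.0)

    def test_large_n_limit_is_aic(self):
        ll, k = -12.5, 4
        assert aicc(ll, k, 10**9) == pytest.approx(-2 * ll + 2 * k, abs=1e-5)

    def test_strictly_decreasing_in_n(self):
        vals = [aicc(-5.0, 3, n) for n in range(6, 30)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            aicc(0.0, 4, 5)


class TestModelSelect:
    def test_delta_zero_two_weights(self):
        delta, w = _akaike_weights(np.array([100.0, 102.0]))
        assert delta.tolist() == [0.0, 2.0]
        assert w[0] == pytest.approx(0.731, abs=5e-4)
        assert w[1] == pytest.approx(0.269, abs=5e-4)

    def test_equal_aicc_splits_weight(self):
        _, w = _akaike_weights(np.array([50.0, 50.0]))
        np.testing.assert_allclose(w, [0.5, 0.5])

    def test_table_structure_and_weight_sum(self, rng):
        env = pd.DataFrame(rng.normal(size=(40, 3)), columns=["a", "b", "c"])
        y = env["a"] * 2 + rng.normal(size=40)
        table = model_select(y, env, ["a", "b", "c"])
        assert len(table.fits) == 8  # 2^3 subsets incl. intercept-only
        assert sum(f.akaike_weight for f in table.fits) == pytest.approx(1.0, abs=1e-12)
        assert table.fits[0].delta == 0.0
        assert any(f.predictors == () for f in table.fits)
        aiccs = [f.aicc for f in table.fits]
        assert aiccs == sorted(aiccs)
        for v in table.predictor_importance.values():
            assert 0.0 <= v <= 1.0

    def test_single_active_predictor_recovered(self, rng):
        # averaged over replicates: the active predictor saturates its summed
        # weight while pure-noise predictors stay near the baseline
        imps = []
        for _ in range(10):
            env = pd.DataFrame(
                rng.normal(size=(120, 4)), columns=["x1", "x2", "x3", "x4"]
            )
            y = 5 + 2 * env["x1"] + rng.normal(scale=1.0, size=120)
            imps.append(model_select(y, env, ["x1", "x2", "x3", "x4"]).predictor_importance)
        mean = {p: np.mean([d[p] for d in imps]) for p in imps[0]}
        assert mean["x1"] > 0.9
        for p in ("x2", "x3", "x4"):
            assert mean[p] < 0.5

    def test_weights_invariant_to_predictor_rescaling(self, rng):
        env = pd.DataFrame(rng.normal(size=(50, 3)), columns=["a", "b", "c"])
        y = env["a"] - env["b"] + rng.normal(size=50)
        t1 = model_select(y, env, ["a", "b", "c"])
        t2 = model_select(y, env * [100.0, 0.01, -3.0] + [5, -2, 0], ["a", "b", "c"])
        w1 = t1.table.sort_values("subset")["weight"].to_numpy()
        w2 = t2.table.sort_values("subset")["weight"].to_numpy()
        np.testing.assert_allclose(w1, w2, atol=1e-10)

    def test_estimator_interface(self, rng):
        env = pd.DataFrame(rng.normal(size=(60, 2)), columns=["a", "b"])
        y = 1 + 3 * env["a"] + rng.normal(size=60)
        sel = AiccModelSelector().fit(env, y)
        assert sel.best_.predictors == ("a",)
        pred = sel.predict(env)
        assert np.corrcoef(pred, y)[0, 1] > 0.9


class TestRefitExcluding:
    def test_absent_group_identical_fit(self, rng):
        x = rng.normal(size=30)
        y = 2 * x + rng.normal(size=30)
        groups = ["g1"] * 15 + ["g2"] * 15
        full = ols_fit(y, x)
        refit = refit_excluding(y, x, groups, "nonexistent")
        assert refit.coefficients["x"] == pytest.approx(full.coefficients["x1"], rel=1e-12)
        assert refit.adjusted_r2 == pytest.approx(full.adjusted_r2, rel=1e-12)

    def test_planted_outlier_group_flips_slope(self):
        rng = np.random.default_rng(11)
        x = np.concatenate([np.linspace(0, 1, 20), np.full(5, 3.0)])
        y = np.concatenate(
            [1.0 - 2.0 * x[:20] + rng.normal(scale=0.05, size=20),
             np.full(5, 8.0) + rng.normal(scale=0.05, size=5)]
        )
        groups = ["main"] * 20 + ["outlier"] * 5
        full = ols_fit(y, x)
        refit = refit_excluding(y, x, groups, "outlier")
        assert full.coefficients["x1"] > 0  # outliers drag slope positive
        assert refit.coefficients["x"] < 0
        assert refit.slope_p_values["x"] < 0.001

    def test_matches_direct_subset_fit(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        groups = ["a"] * 10 + ["b"] * 10
        refit = refit_excluding(y, x, groups, "b")
        direct = ols_fit(y[:10], x[:10], predictors=["x"])
        assert refit.adjusted_r2 == pytest.approx(direct.adjusted_r2, rel=1e-12)


class TestSpearman:
    def test_monotone_transform_perfect(self, rng):
        x = rng.normal(size=25)
        assert spearman(x, np.exp(x)) == pytest.approx(1.0)

    def test_matches_rank_then_pearson_oracle(self, rng):
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert spearman(x, y) == pytest.approx(oracle, rel=1e-10)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValidationError):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_partial_reduces_to_marginal_when_control_uncorrelated(self):
        # population property: z independent of both -> partial ~ marginal
        rng = np.random.default_rng(77)
        x = rng.normal(size=2000)
        y = 0.6 * x + rng.normal(size=2000)
        z = rng.normal(size=2000)
        assert abs(partial_spearman(x, y, z) - spearman(x, y)) < 0.02

    def test_partial_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        x = rng.normal(size=40)
        z = rng.normal(size=40)
        y = 0.5 * x + 0.7 * z + rng.normal(size=40)
        df = pd.DataFrame({"x": x, "y": y, "z": z})
        ref = pingouin.partial_corr(df, x="x", y="y", covar="z", method="spearman")
        assert partial_spearman(x, y, z) == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
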