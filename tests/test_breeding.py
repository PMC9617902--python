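import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from cranecycle import breeding, synth


class TestScalePredictors:
    def test_simple_column(self):
        X, _, _ = breeding.scale_predictors(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))
        assert X["a"].tolist() == [-1.0, 0.0, 1.0]

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"a": rng.normal(3, 5, 50)})
        once, _, _ = breeding.scale_predictors(X)
        twice, _, _ = breeding.scale_predictors(once)
        assert np.allclose(once, twice, atol=1e-12)

    def test_moments(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(10, 3, size=(40, 3)), columns=list("abc"))
        Xs, _, _ = breeding.scale_predictors(X)
        assert np.allclose(Xs.mean(), 0, atol=1e-12)
        assert np.allclose(Xs.std(ddof=1), 1, atol=1e-12)

    def test_constant_column_named(self):
        with pytest.raises(ValueError, match="const_col"):
            breeding.scale_predictors(pd.DataFrame({"a": [1, 2.0], "const_col": [5, 5.0]}))


class TestVifAndCorr:
    def test_orthogonal_columns_all_kept(self):
        X = pd.DataFrame({"a": [1, -1, 1, -1.0], "b": [1, 1, -1, -1.0]})
        cols, report = breeding.vif_screen(X)
        assert cols == ["a", "b"]
        assert all(abs(v - 1.0) < 1e-12 for v in report[0]["vifs"].values())

    def test_vif_closed_form_at_r_058(self):
        # correlation 0.58 -> VIF = 1/(1-0.58^2)
        rng = np.random.default_rng(2)
        n = 20000
        a = rng.normal(size=n)
        b = 0.58 * a + np.sqrt(1 - 0.58 ** 2) * rng.normal(size=n)
        cols, report = breeding.vif_screen(pd.DataFrame({"a": a, "b": b}))
        assert cols == ["a", "b"]
        expect = 1.0 / (1.0 - 0.58 ** 2)
        assert report[0]["vifs"]["a"] == pytest.approx(expect, rel=0.05)

    def test_duplicated_column_dropped(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=50)
        X = pd.DataFrame({"a": a, "b": rng.normal(size=50), "a2": a})
        cols, _ = breeding.vif_screen(X)
        assert len(cols) == 2 and "b" in cols

    def test_corr_check(self):
        a = np.array([1.0, 2, 3, 4])
        same = pd.DataFrame({"a": a, "b": a})
        r, ok = breeding.corr_check(same)
        assert r == pytest.approx(1.0) and not ok
        orth = pd.DataFrame({"a": [1, -1, 1, -1.0], "b": [1, 1, -1, -1.0]})
        r, ok = breeding.corr_check(orth)
        assert r == pytest.approx(0.0, abs=1e-12) and ok

    def test_corr_matches_pearson_oracle(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=30)
        y = 0.4 * x + rng.normal(size=30)
        r, _ = breeding.corr_check(pd.DataFrame({"x": x, "y": y}))
        oracle = abs(np.corrcoef(x, y)[0, 1])
        assert r == pytest.approx(oracle, abs=1e-12)


def _bernoulli_negll(beta, y, A):
    eta = A @ beta
    return float(np.sum(np.log1p(np.exp(eta))) - y @ eta)


class TestFitGLM:
    def test_intercept_only_closed_form(self):
        y = np.array([1] * 7 + [0] * 3, dtype=float)
        fit = breeding.fit_binomial_glm(y, pd.DataFrame(index=range(10)))
        assert fit.coef[0] == pytest.approx(np.log(7 / 3), abs=1e-8)
        assert fit.converged

    def test_aic_identity(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame({"x": rng.normal(size=80)})
        y = (rng.random(80) < 0.5).astype(float)
        fit = breeding.fit_binomial_glm(y, X)
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.k, abs=1e-12)

    def test_separation_flagged(self):
        x = np.array([0.0] * 5 + [1.0] * 5)
        fit = breeding.fit_binomial_glm(x.copy(), pd.DataFrame({"x": x}))
        assert fit.separation
        assert not fit.converged

    def test_deviance_nonincreasing_and_gradient_small(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.normal(size=(200, 3)), columns=list("abc"))
        eta = 0.3 + X["a"] - 0.5 * X["b"]
        y = (rng.random(200) < 1 / (1 + np.exp(-eta))).astype(float)
        import statsmodels.api as sm
        A = np.column_stack([np.ones(200), X.to_numpy()])
        res = sm.GLM(y, A, family=sm.families.Binomial()).fit(maxiter=100, tol=1e-8)
        # entries 0-1 are initialization artifacts, not IRLS iterates
        dev = res.fit_history["deviance"][2:]
        assert all(b <= a + 1e-8 for a, b in zip(dev, dev[1:]))
        mu = res.predict(A)
        grad = A.T @ (y - mu)
        assert np.linalg.norm(grad) < 1e-6

    def test_gaussian_family(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame({"x": rng.normal(size=60)})
        y = 2.0 + 3.0 * X["x"] + rng.normal(0, 0.5, 60)
        fit = breeding.fit_binomial_glm(y.to_numpy(), X, family="gaussian")
        assert fit.coef[1] == pytest.approx(3.0, abs=0.3)
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.k, abs=1e-12)

    def test_nonbinary_rejected(self):
        with pytest.raises(ValueError, match="0/1"):
            breeding.fit_binomial_glm(np.array([0.0, 0.5, 1.0]),
                                      pd.DataFrame({"x": [1, 2, 3.0]}))


class TestAllSubsetsAverage:
    def test_akaike_weight_formula(self):
        d = np.array([100.0, 102.0]) - 100.0
        w = np.exp(-d / 2) / np.exp(-d / 2).sum()
        assert w == pytest.approx([0.7311, 0.2689], abs=1e-4)

    def test_weights_sum_to_one_and_best_delta_zero(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(size=(100, 3)), columns=list("abc"))
        y = (rng.random(100) < 0.5).astype(float)
        res = breeding.all_subsets_average(y, X)
        assert res.models["weight"].sum() == pytest.approx(1.0, abs=1e-12)
        assert res.models["delta_aic"].iloc[0] == 0.0
        assert len(res.models) == 8

    def test_p2_matches_brute_force_oracle(self):
        """Each of the 4 subset AICs equals an independent optimizer's."""
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.normal(size=(60, 2)), columns=["a", "b"])
        y = (rng.random(60) < 1 / (1 + np.exp(-(0.2 + 0.8 * X["a"])))).astype(float)
        res = breeding.all_subsets_average(y, X)
        assert len(res.models) == 4
        for _, row in res.models.iterrows():
            cols = list(row["terms"])
            A = np.column_stack([np.ones(60)] + [X[c].to_numpy() for c in cols])
            opt = minimize(_bernoulli_negll, np.zeros(A.shape[1]),
                           args=(y, A), method="BFGS")
            oracle_aic = 2 * opt.fun + 2 * A.shape[1]
            assert row["aic"] == pytest.approx(oracle_aic, abs=1e-4)

    def test_intercept_only_averaging_is_single_model(self):
        y = np.array([1.0] * 7 + [0.0] * 3)
        res = breeding.all_subsets_average(y, pd.DataFrame(index=range(10)))
        assert len(res.models) == 1
        assert res.coef["(Intercept)"] == pytest.approx(np.log(7 / 3), abs=1e-8)

    def test_top_set_inclusive_at_delta_two(self):
        rng = np.random.default_rng(10)
        X = pd.DataFrame(rng.normal(size=(50, 2)), columns=["a", "b"])
        y = (rng.random(50) < 0.5).astype(float)
        res = breeding.all_subsets_average(y, X, delta_aic=2.0)
        assert (res.top_set["delta_aic"] <= 2.0).all()
        outside = res.models[res.models["delta_aic"] > 2.0]
        assert len(res.top_set) + len(outside) == len(res.models)

    def test_predictor_cap(self):
        X = pd.DataFrame(np.zeros((4, 16)), columns=[f"x{i}" for i in range(16)])
        with pytest.raises(ValueError, match="15"):
            breeding.all_subsets_average(np.zeros(4), X)


class TestRecovery:
    def test_water_effect_recovered_at_large_n(self):
        cfg = synth.NestSimConfig(n_territories=800, years=tuple(range(2014, 2021)),
                                  seed=42)
        nests, truth = synth.simulate_nests(cfg)
        # direct refit oracle: empirical logit slope of hatching on scaled water
        rep = breeding.recover_effects(
            nests, truth["beta"]["hatched"], "hatched", synth.NEST_COVARIATES)
        water = rep[rep["term"] == "water_pct"].iloc[0]
        assert water["sign_match"]
        assert abs(water["estimate"] - 0.6) < 0.1

    def test_null_effect_coverage(self):
        """A zero-effect covariate's model-averaged estimate covers 0 within
        +-1.96 SE in at least 90% of seeded replicates."""
        hits = 0
        n_rep = 50
        for seed in range(n_rep):
            cfg = synth.NestSimConfig(
                n_territories=400, years=(2016,),
                beta={"hatched": {"(Intercept)": 0.2, "water_pct": 0.6}},
                covariate_means={"water_pct": 20.0, "temp_c": 15.0},
                covariate_sds={"water_pct": 8.0, "temp_c": 2.0},
                seed=seed)
            nests, truth = synth.simulate_nests(cfg)
            rep = breeding.recover_effects(
                nests, truth["beta"]["hatched"], "hatched",
                ["water_pct", "temp_c"])
            hits += bool(rep.set_index("term").loc["temp_c", "covered"])
        assert hits / n_rep >= 0.90

    def test_wider_se_at_small_n(self):
        big = synth.NestSimConfig(n_territories=720, years=(2015,), seed=1)
        small = synth.NestSimConfig(n_territories=50, years=(2015,), seed=1)
        reps = {}
        for name, cfg in (("big", big), ("small", small)):
            nests, truth = synth.simulate_nests(cfg)
            rep = breeding.recover_effects(
                nests, truth["beta"]["hatched"], "hatched", synth.NEST_COVARIATES)
            reps[name] = rep.set_index("term").loc["water_pct", "se"]
        assert reps["small"] > reps["big"]
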