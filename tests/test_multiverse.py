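"""Design construction, the three regression universes, and the reduction rule."""

import numpy as np
import pandas as pd
import pytest

from vsmulti import multiverse as mv
from vsmulti.distributions import EXGAUSSIAN, NORMAL, exgauss_rvs, fit_mle
from vsmulti.importance import ImportanceResult


def _factorial_data(rng, n=360):
    return pd.DataFrame({
        "group": rng.choice(["c", "i"], n),
        "set_size": rng.choice([4, 16, 24], n),
        "target": rng.choice(["ab", "p"], n),
        "nystagmus": rng.integers(0, 2, n),
        "age": rng.uniform(5, 18, n),
        "gender": rng.choice(["f", "m"], n),
    })


class TestDesign:
    def test_reference_levels_and_terms(self, rng):
        data = _factorial_data(rng)
        formula = mv.ModelFormula("rt", ("group", "set_size", "target"),
                                  ("nystagmus", "age", "gender"))
        data["rt"] = 1.0
        X, colmap = formula.design(data)
        assert X.columns[0] == "Intercept"
        assert "G[i]" in X.columns and "S[16]" in X.columns
        assert "G[i]:S[24]:T[p]" in X.columns
        assert colmap["G[i]:S[24]:T[p]"] == frozenset({"group", "set_size", "target"})
        assert colmap["a"] == frozenset({"age"})
        # factorial block in G (2) x S (3) x T (2) has 2*3*2 - 1 = 11
        # non-intercept columns, plus 3 mains and the intercept
        assert X.shape[1] == 11 + 3 + 1
        assert formula.describe() == "rt ~ G x S x T + n + a + g"

    def test_design_hash_stability(self, rng):
        data = _factorial_data(rng)
        X1, _ = mv.build_design(data, ("group", "target"))
        X2, _ = mv.build_design(data.copy(), ("group", "target"))
        assert mv.design_hash(X1) == mv.design_hash(X2)

    def test_rank_deficiency_reported_with_columns(self, rng):
        data = _factorial_data(rng)
        data["rt"] = 1.0
        data["nystagmus"] = (data["group"] == "i").astype(int)  # aliased
        formula = mv.ModelFormula("rt", ("group", "nystagmus"))
        with pytest.raises(ValueError, match="aliased"):
            formula.design(data)


class TestQuantile:
    def test_intercept_only_is_the_median(self, rng):
        y = rng.exponential(2.0, 301)
        X = pd.DataFrame({"Intercept": np.ones_like(y)})
        tab = mv.fit_quantile(X, y)
        assert tab.loc["Intercept", "estimate"] == pytest.approx(np.median(y),
                                                                 rel=1e-3)

    def test_noiseless_recovery(self, rng):
        x = rng.uniform(0, 1, 200)
        X = pd.DataFrame({"Intercept": np.ones_like(x), "x": x})
        y = 1.0 + 2.5 * x
        tab = mv.fit_quantile(X, y)
        assert tab["estimate"].to_numpy() == pytest.approx([1.0, 2.5], abs=1e-6)

    def test_group_median_shift_recovered(self, rng):
        hits = 0
        for _ in range(10):
            g = rng.integers(0, 2, 300)
            y = exgauss_rvs(1.0 + 0.5 * g, 0.2, 0.4, 300, rng)
            X = pd.DataFrame({"Intercept": np.ones(300), "g": g.astype(float)})
            tab = mv.fit_quantile(X, y)
            est, se = tab.loc["g", "estimate"], tab.loc["g", "se"]
            hits += abs(est - 0.5) < 1.96 * se
        assert hits >= 9


class TestRobust:
    def test_clean_normal_matches_least_squares(self, rng):
        x = rng.normal(size=400)
        y = 0.5 + 1.2 * x + rng.normal(0, 0.3, 400)
        X = pd.DataFrame({"Intercept": np.ones_like(x), "x": x})
        tab = mv.fit_robust(X, y)
        ols = np.linalg.lstsq(X.to_numpy(), y, rcond=None)[0]
        assert np.allclose(tab["estimate"], ols, rtol=0.01, atol=0.01)

    def test_resists_gross_outliers(self, rng):
        x = rng.normal(size=300)
        y = 1.0 + 2.0 * x + rng.normal(0, 0.3, 300)
        y_cont = y.copy()
        bad = rng.choice(300, 30, replace=False)
        y_cont[bad] += 25.0
        X = pd.DataFrame({"Intercept": np.ones_like(x), "x": x})
        huber = mv.fit_robust(X, y_cont).loc["x", "estimate"]
        ols = np.linalg.lstsq(X.to_numpy(), y_cont, rcond=None)[0][1]
        assert abs(huber - 2.0) < 0.2 * abs(ols - 2.0)

    def test_intercept_only_symmetric_data(self, rng):
        y = rng.normal(3.0, 1.0, 500)
        X = pd.DataFrame({"Intercept": np.ones_like(y)})
        tab = mv.fit_robust(X, y)
        assert tab.loc["Intercept", "estimate"] == pytest.approx(np.mean(y),
                                                                 abs=0.05)


class TestDistributional:
    def test_intercept_only_equals_fit_mle(self, rng):
        y = exgauss_rvs(1.0, 0.2, 0.5, 600, rng)
        X = pd.DataFrame({"Intercept": np.ones_like(y)})
        fit = mv.fit_distributional(X, y, EXGAUSSIAN)
        base = fit_mle(y, EXGAUSSIAN)
        mu_hat = fit["tables"]["mu"].loc["Intercept", "estimate"]
        sig_hat = np.exp(fit["tables"]["sigma"].loc["Intercept", "estimate"])
        nu_hat = np.exp(fit["tables"]["nu"].loc["Intercept", "estimate"])
        assert np.allclose([mu_hat, sig_hat, nu_hat], base.theta_hat,
                           rtol=1e-3, atol=1e-4)

    def test_scale_only_effect_lands_in_sigma_submodel(self, rng):
        hits_sigma = hits_mu = 0
        for _ in range(10):
            g = rng.integers(0, 2, 400)
            y = rng.normal(0.0, np.where(g == 1, 2.0, 1.0))
            X = pd.DataFrame({"Intercept": np.ones(400), "g": g.astype(float)})
            fit = mv.fit_distributional(X, y, NORMAL)
            hits_sigma += fit["tables"]["sigma"].loc["g", "p"] < 0.05
            hits_mu += fit["tables"]["mu"].loc["g", "p"] < 0.05
        assert hits_sigma >= 9
        assert hits_mu <= 3

    def test_location_effect_recovered_with_valid_se(self, rng):
        g = rng.integers(0, 2, 500)
        y = exgauss_rvs(1.0 + 0.5 * g, 0.2, 0.4, 500, rng)
        X = pd.DataFrame({"Intercept": np.ones(500), "g": g.astype(float)})
        fit = mv.fit_distributional(X, y, EXGAUSSIAN)
        tab = fit["tables"]["mu"]
        assert abs(tab.loc["g", "estimate"] - 0.5) < 3 * tab.loc["g", "se"]
        assert tab.loc["g", "p"] < 1e-6


def _fake_result(tables_spec, colmap):
    tables = {}
    for universe, rows in tables_spec.items():
        tables[universe] = pd.DataFrame(rows, index=list(colmap)).astype(float)
    formula = mv.ModelFormula("rt", ())
    return mv.MultiverseResult(formula=formula, tables=tables, colmap=colmap,
                               design_sha256="x")


def _fake_importance(decisions):
    return ImportanceResult(decisions=decisions,
                            importance_history=pd.DataFrame(),
                            shadow_max_history=np.array([]), hits={},
                            n_iterations=10)


class TestReduceModel:
    colmap = {"Intercept": frozenset(),
              "G[i]": frozenset({"group"}),
              "a": frozenset({"age"})}

    def test_confirmed_or_consistently_significant(self):
        # group: tiny p, same sign everywhere -> voted in; age: rejected by
        # the screen and null in regressions -> out
        res = _fake_result({
            u: {"estimate": [1.0, 0.8, 0.0], "se": [0.1] * 3,
                "p": [1e-9, 1e-9, 0.9]}
            for u in ("quantile", "robust", "distributional")
        }, self.colmap)
        imp = _fake_importance({"group": "tentative", "age": "rejected"})
        red = mv.reduce_model(res, imp)
        assert red["retained"] == ["group"]

    def test_rejected_variable_not_resurrected_by_vote(self):
        res = _fake_result({
            u: {"estimate": [1.0, 0.8, 0.5], "se": [0.1] * 3,
                "p": [1e-9, 1e-9, 1e-9]}
            for u in ("quantile", "robust", "distributional")
        }, self.colmap)
        imp = _fake_importance({"group": "confirmed", "age": "rejected"})
        red = mv.reduce_model(res, imp)
        assert red["retained"] == ["group"]
        assert red["audit"]["rejected_veto"] == ["age"]

    def test_all_null_gives_empty_set_with_warning(self):
        res = _fake_result({
            u: {"estimate": [1.0, 0.1, 0.1], "se": [0.1] * 3,
                "p": [1e-9, 0.5, 0.5]}
            for u in ("quantile", "robust", "distributional")
        }, self.colmap)
        imp = _fake_importance({"group": "rejected", "age": "rejected"})
        red = mv.reduce_model(res, imp)
        assert red["retained"] == []
        assert "warning" in red["audit"]

    def test_single_universe_degrades_rule(self):
        res = _fake_result({
            "robust": {"estimate": [1.0, 0.8, 0.0], "se": [0.1] * 3,
                       "p": [1e-9, 1e-9, 0.9]},
        }, self.colmap)
        imp = _fake_importance({"group": "tentative", "age": "tentative"})
        red = mv.reduce_model(res, imp)
        assert red["retained"] == ["group"]
        assert red["audit"]["degraded"]

    def test_sign_flip_blocks_the_vote(self):
        rows = {"quantile": {"estimate": [1.0, 0.8, 0.0], "se": [0.1] * 3,
                             "p": [1e-9, 1e-9, 0.9]},
                "robust": {"estimate": [1.0, -0.8, 0.0], "se": [0.1] * 3,
                           "p": [1e-9, 1e-9, 0.9]},
                "distributional": {"estimate": [1.0, 0.1, 0.0],
                                   "se": [0.1] * 3, "p": [1e-9, 0.5, 0.9]}}
        res = _fake_result(rows, self.colmap)
        imp = _fake_importance({"group": "tentative", "age": "tentative"})
        red = mv.reduce_model(res, imp)
        assert red["retained"] == []


class TestMultiverseEndToEnd:
    def test_universes_share_one_design(self, rng):
        data = _factorial_data(rng, n=300)
        data["rt"] = exgauss_rvs(1.0, 0.2, 0.4, 300, rng)
        formula = mv.ModelFormula("rt", ("group", "target"), ("age",))
        res = mv.fit_multiverse(formula, data, family=EXGAUSSIAN)
        assert set(res.tables) == {"quantile", "robust", "distributional"}
        terms = [tuple(t.index) for t in res.tables.values()]
        assert len(set(terms)) == 1
        assert len(res.design_sha256) == 64
        assert res.agreement.shape[0] == len(terms[0])

    def test_monotone_in_effect_size(self, rng):
        retained = {}
        for shift in (0.35, 0.9):
            data = _factorial_data(rng, n=400)
            g = (data["group"] == "i").to_numpy()
            data["rt"] = exgauss_rvs(1.0 + shift * g, 0.2, 0.4, 400, rng)
            formula = mv.ModelFormula("rt", ("group", "target"), ("age",))
            res = mv.fit_multiverse(formula, data, family=EXGAUSSIAN)
            imp = _fake_importance({"group": "tentative", "target": "tentative",
                                    "age": "tentative"})
            retained[shift] = set(mv.reduce_model(res, imp)["retained"])
        assert retained[0.35] <= retained[0.9]
        assert "group" in retained[0.9]
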