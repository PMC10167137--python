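"""Distributional regression trees: instability tests, partitioning, growth."""

import numpy as np
import pandas as pd
import pytest

from vsmulti.distributions import EXGAUSSIAN, NORMAL, exgauss_rvs, fit_mle
from vsmulti.disttree import (TreeConfig, find_partition, grow,
                              instability_test, median_ci, select_split,
                              to_dot)


def _node_fit(y):
    return fit_mle(y, EXGAUSSIAN)


class TestMedianCI:
    def test_rank_formula_on_one_to_hundred(self):
        out = median_ci(np.arange(1, 101))
        assert out["median"] == 50.5
        assert out["lo"] == 40 and out["hi"] == 60

    def test_constant_sample(self):
        out = median_ci(np.full(30, 2.0))
        assert out["lo"] == out["hi"] == out["median"] == 2.0

    def test_tiny_sample_reports_range(self):
        out = median_ci([3.0, 1.0, 2.0])
        assert out["wide"] and out["lo"] == 1.0 and out["hi"] == 3.0

    def test_coverage_near_nominal(self, rng):
        # binomial order-statistic interval, Normal samples of n=50
        hits = 0
        sims = 2000
        for _ in range(sims):
            out = median_ci(rng.normal(size=50))
            hits += out["lo"] <= 0.0 <= out["hi"]
        assert 0.92 <= hits / sims <= 0.97


class TestInstabilityTest:
    def test_constant_covariate_p_one(self, rng):
        fit = _node_fit(exgauss_rvs(1, 0.2, 0.5, 100, rng))
        out = instability_test(fit.score_matrix, np.full(100, "x"), "nominal")
        assert out["p"] == 1.0
        out = instability_test(fit.score_matrix, np.full(100, 3.3), "numeric")
        assert out["p"] == 1.0

    def test_planted_shift_detected(self, rng):
        detected = 0
        for _ in range(20):
            y1 = exgauss_rvs(1.0, 0.2, 0.3, 100, rng)
            y2 = exgauss_rvs(1.0 + 3 * np.std(np.r_[y1]), 0.2, 0.3, 100, rng)
            y = np.r_[y1, y2]
            cov = np.r_[np.zeros(100), np.ones(100)]
            fit = _node_fit(y)
            out = instability_test(fit.score_matrix, cov, "nominal")
            detected += out["p"] < 1e-4
        assert detected == 20

    def test_numeric_and_categorical_agree_on_structure(self, rng):
        y = np.r_[exgauss_rvs(1.0, 0.2, 0.3, 150, rng),
                  exgauss_rvs(2.0, 0.2, 0.3, 150, rng)]
        cov = np.r_[np.zeros(150), np.ones(150)]
        fit = _node_fit(y)
        p_cat = instability_test(fit.score_matrix, cov, "nominal")["p"]
        p_num = instability_test(fit.score_matrix, cov.astype(float), "numeric")["p"]
        # the numeric p-value is floored at 1/n_paths of the simulated null
        assert p_cat < 1e-6 and p_num <= 1e-4

    def test_mismatched_length_rejected(self, rng):
        fit = _node_fit(exgauss_rvs(1, 0.2, 0.5, 100, rng))
        with pytest.raises(ValueError):
            instability_test(fit.score_matrix, np.zeros(99), "nominal")


class TestSelectSplit:
    def test_strong_covariate_selected_among_nulls(self, rng):
        wins = 0
        for _ in range(10):
            n = 240
            signal = rng.integers(0, 2, n)
            y = exgauss_rvs(1.0 + 0.8 * signal, 0.2, 0.3, n, rng)
            data = pd.DataFrame({
                "signal": signal.astype(str),
                **{f"null{j}": rng.integers(0, 2, n).astype(str)
                   for j in range(4)},
            })
            cfg = TreeConfig(EXGAUSSIAN,
                             {c: "nominal" for c in data.columns})
            sel = select_split(fit_mle(y, EXGAUSSIAN), data, cfg)
            wins += sel is not None and sel["covariate"] == "signal"
        assert wins == 10

    def test_no_covariates_gives_none(self, rng):
        y = exgauss_rvs(1.0, 0.2, 0.3, 100, rng)
        cfg = TreeConfig(EXGAUSSIAN, {"c0": "nominal"})
        data = pd.DataFrame({"c0": ["a"] * 100})
        assert select_split(fit_mle(y, EXGAUSSIAN), data, cfg) is None


class TestFindPartition:
    def test_ordinal_contiguous_shift_recovered(self, rng):
        sizes = rng.choice([4, 16, 24], size=300)
        y = np.where(sizes == 4,
                     exgauss_rvs(1.0, 0.2, 0.3, 300, rng),
                     exgauss_rvs(2.2, 0.25, 0.6, 300, rng))
        cfg = TreeConfig(EXGAUSSIAN, {"set_size": "ordinal"})
        part = find_partition(y, sizes, "ordinal", cfg)
        assert part["left_levels"] == (4,)
        assert part["right_levels"] == (16, 24)

    def test_numeric_matches_exhaustive_closed_form_oracle(self, rng):
        # Normal family: each child's maximised log-likelihood has the
        # closed form -n/2 (log(2 pi sigma_hat^2) + 1)
        n = 30
        x = np.sort(rng.uniform(0, 1, n))
        y = np.where(x < 0.55, 0.0, 1.6) + rng.normal(0, 0.4, n)
        cfg = TreeConfig(NORMAL, {"x": "numeric"}, min_node=10)

        def closed_form_ll(v):
            s2 = np.var(v)
            return -0.5 * len(v) * (np.log(2 * np.pi * s2) + 1.0)

        best_thr, best_ll = None, -np.inf
        vals = np.unique(x)
        for i in range(vals.size - 1):
            thr = 0.5 * (vals[i] + vals[i + 1])
            m = x <= thr
            if m.sum() < 10 or (~m).sum() < 10:
                continue
            ll = closed_form_ll(y[m]) + closed_form_ll(y[~m])
            if ll > best_ll:
                best_thr, best_ll = thr, ll

        part = find_partition(y, x, "numeric", cfg)
        assert part["threshold"] == pytest.approx(best_thr)

    def test_children_never_lose_to_parent(self, rng):
        y = exgauss_rvs(1.0, 0.3, 0.5, 200, rng)
        cov = rng.integers(0, 2, 200).astype(str)
        cfg = TreeConfig(EXGAUSSIAN, {"g": "nominal"})
        parent = fit_mle(y, EXGAUSSIAN)
        part = find_partition(y, cov, "nominal", cfg, init=parent.theta_hat)
        assert part["loglik"] >= parent.loglik - 1e-6

    def test_min_node_respected(self, rng):
        y = exgauss_rvs(1.0, 0.3, 0.5, 50, rng)
        cov = np.array([0] * 5 + [1] * 45)
        cfg = TreeConfig(EXGAUSSIAN, {"g": "nominal"}, min_node=20)
        assert find_partition(y, cov, "nominal", cfg) is None


class TestGrow:
    def _structured(self, rng, n=400):
        g = rng.integers(0, 2, n)
        y = exgauss_rvs(1.0 + 1.0 * g, 0.2, 0.3, n, rng)
        return pd.DataFrame({"y": y, "g": np.where(g == 1, "b", "a"),
                             "noise": rng.integers(0, 2, n).astype(str)})

    def test_max_depth_zero_gives_root_leaf(self, rng):
        data = self._structured(rng)
        cfg = TreeConfig(EXGAUSSIAN, {"g": "nominal", "noise": "nominal"},
                         max_depth=0)
        root = grow(data, "y", cfg)
        assert root.is_leaf and root.node_id == 1

    def test_structured_split_found_and_ids_preorder(self, rng):
        data = self._structured(rng)
        cfg = TreeConfig(EXGAUSSIAN, {"g": "nominal", "noise": "nominal"})
        root = grow(data, "y", cfg)
        assert root.split["covariate"] == "g"
        ids = []

        def walk(n):
            ids.append(n.node_id)
            for c in n.children:
                walk(c)
        walk(root)
        assert ids == sorted(ids) and ids[0] == 1
        assert sum(c.summary["n"] for c in root.children) == root.summary["n"]

    def test_deterministic_serialization(self, rng):
        data = self._structured(rng)
        cfg = TreeConfig(EXGAUSSIAN, {"g": "nominal", "noise": "nominal"})
        a = grow(data, "y", cfg).to_json()
        b = grow(data, "y", cfg).to_json()
        assert a == b

    def test_permuting_covariates_destroys_structure(self, rng):
        hits = 0
        for _ in range(5):
            data = self._structured(rng)
            data["g"] = rng.permutation(data["g"].to_numpy())
            cfg = TreeConfig(EXGAUSSIAN, {"g": "nominal", "noise": "nominal"})
            root = grow(data, "y", cfg)
            hits += root.is_leaf
        assert hits >= 4

    def test_leaf_refit_reproduces_theta(self, rng):
        data = self._structured(rng)
        cfg = TreeConfig(EXGAUSSIAN, {"g": "nominal", "noise": "nominal"})
        root = grow(data, "y", cfg)
        leaf = root.leaves()[0]
        refit = fit_mle(data["y"].to_numpy()[leaf.data_index], EXGAUSSIAN,
                        init=root.model.theta_hat)
        assert np.allclose(refit.theta_hat, leaf.model.theta_hat,
                           rtol=1e-4, atol=1e-5)

    def test_missing_covariate_errors(self, rng):
        data = self._structured(rng)
        cfg = TreeConfig(EXGAUSSIAN, {"absent": "nominal"})
        with pytest.raises(ValueError, match="absent"):
            grow(data, "y", cfg)

    def test_dot_export_reports_node_summaries(self, rng):
        data = self._structured(rng)
        cfg = TreeConfig(EXGAUSSIAN, {"g": "nominal", "noise": "nominal"})
        dot = to_dot(grow(data, "y", cfg))
        assert dot.startswith("digraph")
        assert "n = " in dot and "->" in dot


class TestConfigValidation:
    def test_min_node_floor(self):
        with pytest.raises(ValueError, match="min_node"):
            TreeConfig(EXGAUSSIAN, {"g": "nominal"}, min_node=5)

    def test_alpha_range(self):
        with pytest.raises(ValueError):
            TreeConfig(EXGAUSSIAN, {"g": "nominal"}, alpha=1.5)

    def test_unknown_kind(self):
        with pytest.raises(ValueError, match="kind"):
            TreeConfig(EXGAUSSIAN, {"g": "circular"})
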