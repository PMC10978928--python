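"""Designs, OLS, adjusted-R2 variance partitioning and residual maps."""
import numpy as np
import pandas as pd
import pytest

import biogeodiv as bg
from biogeodiv import inference as inf


def _env_table(rng, n):
    cells = [f"c{i:03d}" for i in range(n)]
    lat = np.linspace(0, 1, n)
    env = pd.DataFrame(index=cells)
    env["t1"] = 10 - 8 * lat + rng.normal(0, 0.5, n)
    env["t2"] = 3 + 5 * lat + rng.normal(0, 0.5, n)
    env["precip_a"] = (4 * (1 - lat) + 1 + rng.normal(0, 0.3, n).clip(-0.9)) ** 2
    env["precip_b"] = (2 * (1 - lat) + 1 + rng.normal(0, 0.3, n).clip(-0.9)) ** 2
    env["t3"] = rng.normal(0, 1, n)
    env["mean_elevation"] = rng.uniform(0, 1000, n)
    env["elevation_range"] = rng.uniform(50, 500, n)
    env["landmass_area"] = np.exp(rng.normal(10, 1, n))
    return env


class TestClimatePca:
    def test_perfectly_correlated_pair_loads_one_component(self):
        cells = [f"c{i}" for i in range(30)]
        x = np.linspace(0, 1, 30)
        env = pd.DataFrame({"a": x, "b": 2 * x + 1,
                            "mean_elevation": x, "elevation_range": x,
                            "landmass_area": np.ones(30)}, index=cells)
        scores, prop, _ = inf.climate_pca(env, (), n_components=2)
        assert prop[0] == pytest.approx(1.0)
        assert prop[1] == pytest.approx(0.0, abs=1e-12)

    def test_constant_variable_named_in_error(self):
        env = pd.DataFrame({"a": np.arange(10.0), "b": np.ones(10),
                            "mean_elevation": np.arange(10.0),
                            "elevation_range": np.arange(10.0),
                            "landmass_area": np.ones(10)},
                           index=[f"c{i}" for i in range(10)])
        with pytest.raises(ValueError, match="'b'"):
            inf.climate_pca(env, (), n_components=2)

    def test_matches_sklearn_pca(self):
        PCA = pytest.importorskip("sklearn.decomposition").PCA
        rng = np.random.default_rng(0)
        env = _env_table(rng, 60)
        scores, prop, _ = inf.climate_pca(env, ["precip_a", "precip_b"], 4)
        X = env[["t1", "t2", "precip_a", "precip_b", "t3"]].to_numpy().copy()
        X[:, 2:4] = np.sqrt(X[:, 2:4])
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        ref = PCA(n_components=4).fit(Z)
        ref_scores = ref.transform(Z)
        for j in range(4):
            dot = np.dot(scores.iloc[:, j], ref_scores[:, j])
            np.testing.assert_allclose(scores.iloc[:, j],
                                       np.sign(dot) * ref_scores[:, j], atol=1e-8)
        np.testing.assert_allclose(prop, ref.explained_variance_ratio_, atol=1e-10)

    def test_sqrt_applied_to_flagged_variables_only(self):
        rng = np.random.default_rng(1)
        env = _env_table(rng, 40)
        s1, _, _ = inf.climate_pca(env, ["precip_a", "precip_b"], 2)
        s2, _, _ = inf.climate_pca(env, [], 2)
        assert not np.allclose(s1.to_numpy(), s2.to_numpy())


class TestDesigns:
    def test_env_design_row_arithmetic(self):
        cells = ["c0"]
        env = pd.DataFrame({"mean_elevation": [2.0], "elevation_range": [3.0],
                            "landmass_area": [np.e]}, index=cells)
        scores = pd.DataFrame([[1.0, 0.0, 0.0, 0.0]], index=cells,
                              columns=["PC1", "PC2", "PC3", "PC4"])
        X = inf.build_env_design(env, scores)
        assert len(X.columns) == 12
        np.testing.assert_allclose(
            X.data.loc["c0"].to_numpy(),
            [1, 0, 0, 0, 1, 0, 0, 0, 2, 4, 3, 1.0])

    def test_nonpositive_area_rejected(self):
        env = pd.DataFrame({"mean_elevation": [1.0], "elevation_range": [1.0],
                            "landmass_area": [0.0]}, index=["c0"])
        with pytest.raises(ValueError, match="landmass_area"):
            inf.validate_env_table(env)

    def test_isolation_trend_surface_row(self):
        res = bg.OrdinationResult(ids=["c0", "c1"],
                                  coordinates=np.array([[1.0, 2.0, 3.0],
                                                        [0.0, 0.0, 0.0]]),
                                  stress=0.1, n_starts=1, best_start=0,
                                  converged=True, seed=0)
        X = inf.build_isolation_design(res)
        assert len(X.columns) == 9
        np.testing.assert_allclose(X.data.loc["c0"].to_numpy(),
                                   [1, 2, 3, 1, 4, 9, 2, 3, 6])
        np.testing.assert_allclose(X.data.loc["c1"].to_numpy(), np.zeros(9))

    def test_non_three_axes_generalized_with_warning(self):
        res = bg.OrdinationResult(ids=["a", "b", "c"],
                                  coordinates=np.arange(6.0).reshape(3, 2),
                                  stress=0.1, n_starts=1, best_start=0,
                                  converged=True, seed=0)
        with pytest.warns(UserWarning, match="k=2"):
            X = inf.build_isolation_design(res)
        assert len(X.columns) == 5  # 2 linear + 2 quadratic + 1 interaction

    def test_realm_dummies(self):
        realms = pd.Series({"c1": "Nea", "c2": "Aus", "c3": "Neo", "c4": "Aus"})
        X = inf.build_realm_design(realms)
        assert X.columns == ["realm_Nea", "realm_Neo"]
        np.testing.assert_allclose(X.data.loc["c2"].to_numpy(), [0, 0])
        assert np.linalg.matrix_rank(X.data.to_numpy()) == 2

    def test_single_realm_rejected(self):
        with pytest.raises(ValueError):
            inf.build_realm_design(pd.Series({"c1": "Aus", "c2": "Aus"}))


class TestOlsFit:
    def test_exact_linear_relationship(self):
        rng = np.random.default_rng(0)
        cells = [f"c{i}" for i in range(20)]
        X = inf.DesignMatrix(cells, pd.DataFrame(
            rng.normal(size=(20, 3)), index=cells, columns=list("abc")))
        beta = np.array([2.0, -1.0, 0.5])
        y = pd.Series(X.data.to_numpy() @ beta + 4.0, index=cells)
        fit = inf.ols_fit(X, y)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.adj_r2 == pytest.approx(1.0)
        np.testing.assert_allclose(fit.residuals, 0, atol=1e-9)
        np.testing.assert_allclose(fit.coefficients[list("abc")], beta, atol=1e-9)

    def test_pure_noise_has_nonpositive_adjusted_r2(self):
        rng = np.random.default_rng(1)
        cells = [f"c{i}" for i in range(200)]
        X = inf.DesignMatrix(cells, pd.DataFrame(
            rng.normal(size=(200, 5)), index=cells,
            columns=[f"x{j}" for j in range(5)]))
        y = pd.Series(rng.normal(size=200), index=cells)
        fit = inf.ols_fit(X, y)
        assert fit.r2 < 0.1
        assert fit.adj_r2 < fit.r2

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(2)
        cells = [f"c{i}" for i in range(50)]
        M = rng.normal(size=(50, 4))
        X = inf.DesignMatrix(cells, pd.DataFrame(
            M, index=cells, columns=[f"x{j}" for j in range(4)]))
        y = pd.Series(M @ [1, 2, 3, 4] + rng.normal(size=50), index=cells)
        fit = inf.ols_fit(X, y)
        ref = sm.OLS(y.to_numpy(), sm.add_constant(M)).fit()
        np.testing.assert_allclose(fit.coefficients.to_numpy(), ref.params,
                                   atol=1e-9)
        assert fit.r2 == pytest.approx(ref.rsquared, abs=1e-10)
        assert fit.adj_r2 == pytest.approx(ref.rsquared_adj, abs=1e-10)

    def test_collinear_columns_reported(self):
        cells = [f"c{i}" for i in range(10)]
        x = np.arange(10.0)
        X = inf.DesignMatrix(cells, pd.DataFrame(
            {"a": x, "twice_a": 2 * x}, index=cells))
        y = pd.Series(x, index=cells)
        with pytest.raises(ValueError, match="twice_a"):
            inf.ols_fit(X, y)

    def test_adjusted_r2_formula(self):
        rng = np.random.default_rng(3)
        cells = [f"c{i}" for i in range(30)]
        X = inf.DesignMatrix(cells, pd.DataFrame(
            rng.normal(size=(30, 3)), index=cells, columns=list("abc")))
        y = pd.Series(rng.normal(size=30), index=cells)
        fit = inf.ols_fit(X, y)
        expected = 1 - (1 - fit.r2) * (fit.n - 1) / (fit.n - fit.p - 1)
        assert fit.adj_r2 == pytest.approx(expected, abs=1e-12)


class TestVariancePartition:
    def _orthogonal_designs(self, n=120, seed=0):
        rng = np.random.default_rng(seed)
        cells = [f"c{i}" for i in range(n)]
        M = rng.normal(size=(n, 4))
        Q, _ = np.linalg.qr(M)
        X_env = inf.DesignMatrix(cells, pd.DataFrame(
            Q[:, :2], index=cells, columns=["e1", "e2"]))
        X_iso = inf.DesignMatrix(cells, pd.DataFrame(
            Q[:, 2:], index=cells, columns=["i1", "i2"]))
        return cells, X_env, X_iso, Q

    def test_partition_identity_exact(self):
        cells, X_env, X_iso, Q = self._orthogonal_designs()
        rng = np.random.default_rng(1)
        y = pd.Series(Q @ [1, 2, 3, 4] + rng.normal(size=len(cells)), index=cells)
        part, *_ = inf.variance_partition(y, X_env, X_iso)
        assert part.unique_env + part.unique_iso + part.shared == pytest.approx(
            part.adj_r2_global, abs=1e-12)

    def test_env_only_signal_gives_no_unique_isolation(self):
        cells, X_env, X_iso, Q = self._orthogonal_designs(seed=2)
        y = pd.Series(Q[:, 0] * 3.0, index=cells)  # purely env-driven
        part, *_ = inf.variance_partition(y, X_env, X_iso)
        assert abs(part.unique_iso) < 0.02
        assert part.adj_r2_env == pytest.approx(1.0)

    def test_orthogonal_signals_split_cleanly(self):
        cells, X_env, X_iso, Q = self._orthogonal_designs(seed=3)
        y = pd.Series(2.0 * Q[:, 0] + 1.0 * Q[:, 2], index=cells)
        part, *_ = inf.variance_partition(y, X_env, X_iso)
        yc = y - y.mean()
        env_share = 4.0 * (Q[:, 0] @ Q[:, 0]) / (yc @ yc)
        assert part.shared == pytest.approx(0.0, abs=0.05)
        assert part.unique_env == pytest.approx(env_share, abs=0.05)

    def test_duplicated_designs_share_everything(self):
        rng = np.random.default_rng(4)
        cells = [f"c{i}" for i in range(60)]
        M = rng.normal(size=(60, 3))
        X1 = inf.DesignMatrix(cells, pd.DataFrame(
            M, index=cells, columns=["a", "b", "c"]))
        X2 = inf.DesignMatrix(cells, pd.DataFrame(
            M + rng.normal(0, 1e-9, M.shape), index=cells,
            columns=["a2", "b2", "c2"]))
        y = pd.Series(M @ [1, 1, 1] + rng.normal(size=60), index=cells)
        part, *_ = inf.variance_partition(y, X1, X2)
        # the global model carries twice the df penalty, so the match is
        # only approximate on the adjusted scale
        assert part.shared == pytest.approx(part.adj_r2_global, abs=0.02)
        assert abs(part.unique_env) < 0.02 and abs(part.unique_iso) < 0.02


class TestResidualsAndSummaries:
    def test_identical_fits_give_zero_difference(self):
        rng = np.random.default_rng(0)
        cells = [f"c{i}" for i in range(20)]
        X = inf.DesignMatrix(cells, pd.DataFrame(
            rng.normal(size=(20, 2)), index=cells, columns=["a", "b"]))
        y = pd.Series(rng.normal(size=20), index=cells)
        fit = inf.ols_fit(X, y)
        np.testing.assert_allclose(inf.residual_difference(fit, fit), 0)

    def test_per_cell_definition(self):
        fit_env = inf.ModelFit(pd.Series(dtype=float),
                               pd.Series({"c1": 0.0}),
                               pd.Series({"c1": -4.0}), 0.5, 0.4, 10, 2)
        fit_glob = inf.ModelFit(pd.Series(dtype=float),
                                pd.Series({"c1": 0.0}),
                                pd.Series({"c1": 1.0}), 0.6, 0.5, 10, 2)
        assert inf.residual_difference(fit_env, fit_glob)["c1"] == pytest.approx(3.0)

    def test_cell_mismatch_rejected(self):
        f1 = inf.ModelFit(pd.Series(dtype=float), pd.Series({"c1": 0.0}),
                          pd.Series({"c1": 1.0}), 0, 0, 5, 1)
        f2 = inf.ModelFit(pd.Series(dtype=float), pd.Series({"c2": 0.0}),
                          pd.Series({"c2": 1.0}), 0, 0, 5, 1)
        with pytest.raises(ValueError):
            inf.residual_difference(f1, f2)

    def test_prediction_summary_arithmetic(self):
        fit = inf.ModelFit(pd.Series(dtype=float),
                           pd.Series({"c1": 10.0, "c2": 20.0, "c3": 30.0}),
                           pd.Series({"c1": 0.0, "c2": 0.0, "c3": 0.0}),
                           1, 1, 3, 1)
        y = pd.Series({"c1": 5.0, "c2": 10.0, "c3": 15.0})
        s = inf.prediction_summary(fit, y, ["c1", "c2", "c3"])
        assert s["median_predicted"] == 20.0
        assert s["median_observed"] == 10.0
        assert s["percent_difference"] == pytest.approx(50.0)

    def test_prediction_summary_zero_difference_when_equal(self):
        fit = inf.ModelFit(pd.Series(dtype=float),
                           pd.Series({"c1": 7.0, "c2": 9.0}),
                           pd.Series({"c1": 0.0, "c2": 0.0}), 1, 1, 2, 1)
        y = pd.Series({"c1": 7.0, "c2": 9.0})
        assert inf.prediction_summary(fit, y, ["c1", "c2"])["percent_difference"] == 0

    def test_empty_subset_rejected(self):
        fit = inf.ModelFit(pd.Series(dtype=float), pd.Series({"c1": 1.0}),
                           pd.Series({"c1": 0.0}), 1, 1, 1, 0)
        with pytest.raises(ValueError):
            inf.prediction_summary(fit, pd.Series({"c1": 1.0}), [])


def test_delta_adjr2_screen():
    rng = np.random.default_rng(5)
    cells = [f"c{i}" for i in range(100)]
    base = inf.DesignMatrix(cells, pd.DataFrame(
        {"x": rng.normal(size=100)}, index=cells))
    useful = inf.DesignMatrix(cells, pd.DataFrame(
        {"u": rng.normal(size=100)}, index=cells))
    noise = inf.DesignMatrix(cells, pd.DataFrame(
        {"v": rng.normal(size=100)}, index=cells))
    y = pd.Series(base.data["x"] + 2 * useful.data["u"]
                  + 0.3 * rng.normal(size=100), index=cells)
    gain_u, keep_u = inf.delta_adjr2(y, base, useful)
    gain_v, keep_v = inf.delta_adjr2(y, base, noise)
    assert keep_u and gain_u > 0.5
    assert not keep_v
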