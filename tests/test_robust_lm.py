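"""Cluster-robust regression: design building, OLS batch, sandwich, Wald."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from longewas.config import AnalysisConfig
from longewas.robust_lm import (
    ClusterIndex,
    DesignMatrix,
    RankDeficiencyError,
    build_design,
    cluster_robust_variance,
    fit_ols_batch,
    fit_robust_batch,
    wald_test,
)

from conftest import make_dataset


def sandwich_loop(X, resid, codes, correction=False):
    """Literal per-cluster double-loop oracle: V = B [sum_j w_j' w_j] B."""
    bread = np.linalg.inv(X.T @ X)
    p = X.shape[1]
    meat = np.zeros((p, p))
    m = len(np.unique(codes))
    for j in np.unique(codes):
        w = np.zeros(p)
        for k in np.where(codes == j)[0]:
            w += resid[k] * X[k]
        meat += np.outer(w, w)
    if correction:
        meat *= m / (m - 1)
    return bread @ meat @ bread


def random_instance(rng, m=None, p=None):
    m = m or rng.integers(3, 11)
    p = p or rng.integers(2, 5)
    sizes = rng.integers(1, 5, size=m)
    n = sizes.sum()
    X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
    codes = np.repeat(np.arange(m), sizes)
    y = rng.normal(size=n)
    return X, codes, y


class TestBuildDesign:
    def test_primary_design_shape_and_centering(self, analysis_config):
        ds = make_dataset(n_individuals=2, ages=(10, 12, 14, 16, 18))
        design, clusters = build_design(ds, analysis_config)
        assert design.X.shape == (10, 4)
        assert design.columns == ["intercept", "exposure", "age", "exposure:age"]
        assert design.age_origin == 10.0
        assert design.X[:, 2].min() == 0.0  # age centred at baseline
        np.testing.assert_array_equal(design.X[:, 3], design.X[:, 1] * design.X[:, 2])
        assert clusters.m == 2

    def test_constant_exposure_raises_named_error(self, analysis_config):
        ds = make_dataset(n_individuals=3, ages=(10, 12), exposure=[1, 1, 1])
        with pytest.raises(RankDeficiencyError, match="exposure"):
            build_design(ds, analysis_config)

    def test_covariate_collinear_with_intercept_raises(self, analysis_config):
        ds = make_dataset(n_individuals=4, ages=(10, 12))
        ds.samples["ones"] = 1.0
        cfg = dataclasses.replace(analysis_config, covariates=("ones",))
        with pytest.raises(RankDeficiencyError, match="ones"):
            build_design(ds, cfg)


class TestOLSBatch:
    def test_exact_fit_recovers_column(self, analysis_config):
        ds = make_dataset(n_individuals=4, ages=(10, 12, 14))
        design, _ = build_design(ds, analysis_config)
        y = design.X[:, 2].copy()  # y identically the age column
        fit = fit_ols_batch(y[None, :], design)
        np.testing.assert_allclose(fit.coef[0], [0, 0, 1, 0], atol=1e-12)
        np.testing.assert_allclose(fit.residuals[0], 0, atol=1e-12)

    def test_intercept_only_gives_mean(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=12)
        design = DesignMatrix(X=np.ones((12, 1)), columns=["intercept"], age_origin=0.0)
        fit = fit_ols_batch(y[None, :], design)
        assert fit.coef[0, 0] == pytest.approx(y.mean(), abs=1e-12)

    def test_matches_normal_equations_oracle(self, analysis_config):
        rng = np.random.default_rng(7)
        ds = make_dataset(n_individuals=4, ages=(10, 12, 14, 16, 18), rng=rng)
        design, _ = build_design(ds, analysis_config)
        y = rng.normal(size=20)
        fit = fit_ols_batch(y[None, :], design)
        X = design.X
        expected = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(fit.coef[0], expected, rtol=1e-10)

    def test_too_few_rows_flags_unfit(self, analysis_config):
        ds = make_dataset(n_individuals=2, ages=(10, 12), n_cpgs=2)
        ds.beta[0, 1:] = np.nan  # one usable row < 4 parameters
        design, _ = build_design(ds, analysis_config)
        fit = fit_ols_batch(ds.beta, design)
        assert not fit.ok[0] and fit.ok[1]

    def test_batch_equals_per_cpg_loop(self, analysis_config):
        rng = np.random.default_rng(9)
        ds = make_dataset(n_individuals=10, ages=(10, 14, 18), n_cpgs=50, rng=rng)
        design, _ = build_design(ds, analysis_config)
        batch = fit_ols_batch(ds.beta, design)
        for i in range(ds.n_cpgs):
            single = fit_ols_batch(ds.beta[i][None, :], design)
            np.testing.assert_allclose(batch.coef[i], single.coef[0], atol=1e-12)


class TestSandwich:
    def test_zero_residuals_give_zero_variance(self, analysis_config):
        ds = make_dataset(n_individuals=3, ages=(10, 12))
        design, clusters = build_design(ds, analysis_config)
        resid = np.zeros((1, 6))
        V, m, _ = cluster_robust_variance(design, resid, clusters)
        np.testing.assert_array_equal(V[0], 0)
        assert m[0] == 3

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X, codes, y = random_instance(rng)
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        design = DesignMatrix(X=X, columns=[f"c{i}" for i in range(X.shape[1])],
                              age_origin=0.0)
        ci = ClusterIndex(codes=codes, ids=sorted(set(codes)))
        for corr in (False, True):
            V, _, _ = cluster_robust_variance(design, resid[None, :], ci,
                                              correction=corr)
            expected = sandwich_loop(X, resid, codes, correction=corr)
            np.testing.assert_allclose(V[0], expected, atol=1e-12)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        sizes=st.lists(st.integers(1, 4), min_size=3, max_size=8),
        seed=st.integers(0, 2**16),
    )
    def test_matches_loop_for_arbitrary_cluster_structures(self, sizes, seed):
        # property: the vectorized sandwich equals the per-cluster loop for
        # any partition of the rows into clusters
        rng = np.random.default_rng(seed)
        n = sum(sizes)
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        codes = np.repeat(np.arange(len(sizes)), sizes)
        resid = rng.normal(size=n)
        design = DesignMatrix(X=X, columns=["a", "b", "c"], age_origin=0.0)
        ci = ClusterIndex(codes=codes, ids=list(range(len(sizes))))
        V, _, _ = cluster_robust_variance(design, resid[None, :], ci)
        np.testing.assert_allclose(V[0], sandwich_loop(X, resid, codes), atol=1e-12)

    def test_five_clusters_three_obs_fixed_residuals(self):
        # fixed small instance fully checked against the literal loop
        rng = np.random.default_rng(42)
        X = np.column_stack([np.ones(15), rng.normal(size=(15, 2))])
        codes = np.repeat(np.arange(5), 3)
        resid = rng.normal(size=15)
        design = DesignMatrix(X=X, columns=["a", "b", "c"], age_origin=0.0)
        ci = ClusterIndex(codes=codes, ids=list(range(5)))
        V, m, _ = cluster_robust_variance(design, resid[None, :], ci)
        np.testing.assert_allclose(V[0], sandwich_loop(X, resid, codes), atol=1e-12)
        assert m[0] == 5

    def test_singleton_clusters_reproduce_hc0(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        n = 40
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        y = rng.normal(size=n)
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        design = DesignMatrix(X=X, columns=["a", "b", "c"], age_origin=0.0)
        ci = ClusterIndex(codes=np.arange(n), ids=list(range(n)))
        V, _, _ = cluster_robust_variance(design, resid[None, :], ci)
        hc0 = sm.OLS(y, X).fit(cov_type="HC0").cov_params()
        np.testing.assert_allclose(V[0], np.asarray(hc0), atol=1e-14)

    def test_matches_statsmodels_cluster_covariance(self, analysis_config):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(21)
        ds = make_dataset(n_individuals=20, ages=(10, 14, 18), n_cpgs=1, rng=rng)
        design, clusters = build_design(ds, analysis_config)
        fit = fit_ols_batch(ds.beta, design)
        V, _, _ = cluster_robust_variance(design, fit.residuals, clusters)
        res = sm.OLS(ds.beta[0], design.X).fit(
            cov_type="cluster",
            cov_kwds={"groups": clusters.codes, "use_correction": False},
        )
        np.testing.assert_allclose(V[0], np.asarray(res.cov_params()), atol=1e-14)

    def test_missing_cluster_reduces_m(self, analysis_config):
        ds = make_dataset(n_individuals=4, ages=(10, 12, 14), n_cpgs=1)
        ds.beta[0, :3] = np.nan  # first individual fully missing
        design, clusters = build_design(ds, analysis_config)
        fit = fit_ols_batch(ds.beta, design)
        _, m, _ = cluster_robust_variance(design, fit.residuals, clusters)
        assert m[0] == 3

    def test_v_symmetric_psd(self, analysis_config):
        rng = np.random.default_rng(15)
        ds = make_dataset(n_individuals=12, ages=(10, 14, 18), n_cpgs=6, rng=rng)
        design, clusters = build_design(ds, analysis_config)
        fit = fit_ols_batch(ds.beta, design)
        V, _, _ = cluster_robust_variance(design, fit.residuals, clusters)
        for v in V:
            np.testing.assert_allclose(v, v.T, atol=1e-15)
            assert np.all(np.linalg.eigvalsh(v) >= -1e-15)


class TestWald:
    def test_zero_estimate_gives_p_one(self, analysis_config):
        se, stat, p = wald_test(
            np.array([[0.0]]), np.array([[[1.0]]]), np.array([10]), analysis_config
        )
        assert stat[0, 0] == 0.0 and p[0, 0] == pytest.approx(1.0)

    def test_normal_reference_quantile(self, analysis_config):
        z = 1.959964
        se, stat, p = wald_test(
            np.array([[z]]), np.array([[[1.0]]]), np.array([100]), analysis_config
        )
        assert p[0, 0] == pytest.approx(0.05, abs=1e-6)

    def test_t_reference_quantile(self, analysis_config):
        cfg = dataclasses.replace(analysis_config, df_method="t_clusters_minus_p")
        # m - p = 10: t quantile 2.228 gives p = 0.05
        se, stat, p = wald_test(
            np.array([[2.228139]]), np.array([[[1.0]]]), np.array([11]), cfg
        )
        assert p[0, 0] == pytest.approx(0.05, abs=1e-5)

    def test_degenerate_se_conventions(self, analysis_config):
        with pytest.warns(RuntimeWarning):
            se, stat, p = wald_test(
                np.array([[0.5, 0.0]]),
                np.array([np.zeros((2, 2))]),
                np.array([10]),
                analysis_config,
            )
        assert p[0, 0] == 0.0 and p[0, 1] == 1.0


class TestEndToEndProperties:
    def test_permutation_invariance(self, analysis_config):
        rng = np.random.default_rng(33)
        ds = make_dataset(n_individuals=8, ages=(10, 14, 18), n_cpgs=5, rng=rng)
        res1 = fit_robust_batch(ds, analysis_config)
        perm = rng.permutation(ds.n_obs)
        from longewas.datamodel import LongitudinalDataset

        ds2 = LongitudinalDataset(
            ds.cpg_ids, ds.beta[:, perm], ds.samples.iloc[perm].reset_index(drop=True)
        )
        res2 = fit_robust_batch(ds2, analysis_config)
        for col in ("estimate", "se", "p_value"):
            np.testing.assert_allclose(
                res1.table[col].to_numpy(), res2.table[col].to_numpy(), atol=1e-12
            )

    def test_scaling_y_scales_estimates_not_pvalues(self, analysis_config):
        rng = np.random.default_rng(4)
        ds = make_dataset(n_individuals=8, ages=(10, 14, 18), n_cpgs=3, rng=rng)
        res1 = fit_robust_batch(ds, analysis_config)
        from longewas.datamodel import LongitudinalDataset

        ds2 = LongitudinalDataset(ds.cpg_ids, ds.beta * 3.0, ds.samples)
        res2 = fit_robust_batch(ds2, analysis_config)
        np.testing.assert_allclose(
            res2.table["estimate"], res1.table["estimate"] * 3.0, rtol=1e-10
        )
        np.testing.assert_allclose(res2.table["se"], res1.table["se"] * 3.0, rtol=1e-10)
        np.testing.assert_allclose(
            res2.table["p_value"], res1.table["p_value"], atol=1e-12
        )

    def test_type1_calibrated_with_independent_errors(self, analysis_config):
        # singleton clusters + iid noise: Wald test should hold its level
        rng = np.random.default_rng(99)
        n, reps = 200, 2500
        X = np.column_stack([np.ones(n), rng.integers(0, 2, size=n)])
        design = DesignMatrix(X=X, columns=["intercept", "exposure"], age_origin=0.0)
        ci = ClusterIndex(codes=np.arange(n), ids=list(range(n)))
        Y = rng.normal(size=(reps, n))
        fit = fit_ols_batch(Y, design)
        V, m, _ = cluster_robust_variance(design, fit.residuals, ci)
        _, _, p = wald_test(fit.coef, V, m, analysis_config)
        rate = np.mean(p[:, 1] < 0.05)
        mc_sd = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < 3 * mc_sd
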