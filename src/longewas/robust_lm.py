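"""Vectorized linear regression with cluster-robust (sandwich) standard errors.

Fitting one OLS model per CpG across all repeated measures gives valid
point estimates of the trajectory fixed effects; because the repeated
measures of an individual share random intercept/slope deviations, the
residuals are correlated within individuals and classical OLS standard
errors are wrong.  The cluster-robust sandwich estimator

    V = (X'X)^-1 [ sum_j w_j' w_j ] (X'X)^-1,    w_j = sum_{k in j} e_k x_k

(clusters j = individuals, e_k the OLS residuals, x_k the predictor row)
is consistent under arbitrary within-individual residual correlation.  The
whole epigenome shares one design matrix, so a single factorization of X
serves every CpG with complete data; CpGs with missing values fall back to
a per-missingness-pattern refit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .datamodel import LongitudinalDataset, ResultTable, ValidationError

BASE_COLUMNS = ("intercept", "exposure", "age", "exposure:age")

#: condition number above which a design warning is emitted
COND_WARN = 1e8


class RankDeficiencyError(ValidationError):
    """The design matrix is not full column rank."""


@dataclass
class DesignMatrix:
    """Observation-level design [1, z, x, z*x, covariates...] with age centred."""

    X: np.ndarray
    columns: list[str]
    age_origin: float

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass
class ClusterIndex:
    """Partition of design rows into individuals (clusters)."""

    codes: np.ndarray  # integer cluster code per row
    ids: list

    @property
    def m(self) -> int:
        return len(self.ids)

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.codes, minlength=self.m)


def _check_full_rank(X: np.ndarray, columns: list[str]) -> None:
    # QR diagonal pinpoints the first column collinear with its predecessors
    R = np.linalg.qr(X, mode="r")
    diag = np.abs(np.diag(R))
    scale = np.linalg.norm(X, axis=0)
    scale[scale == 0] = 1.0
    bad = np.where(diag / scale < 1e-10)[0]
    if len(bad):
        raise RankDeficiencyError(
            f"design matrix is rank deficient: column {columns[bad[0]]!r} is "
            "collinear with the preceding columns"
        )


def build_design(
    dataset: LongitudinalDataset, config: AnalysisConfig
) -> tuple[DesignMatrix, ClusterIndex]:
    """Build the trajectory design and the individual cluster index.

    Columns are intercept, exposure, centred age, exposure x centred age,
    then any configured covariates.  Age is centred at ``config.age_origin``
    (default: minimum age present) so the exposure main effect is the
    baseline effect.
    """
    ages = dataset.ages
    origin = config.age_origin if config.age_origin is not None else float(ages.min())
    x = ages - origin
    z = dataset.exposure
    cols = [np.ones_like(x), z, x, z * x]
    names = list(BASE_COLUMNS)
    for cov in config.covariates:
        if cov not in dataset.samples.columns:
            raise ValidationError(
                f"covariate {cov!r} named in config is absent from the sample sheet"
            )
        cols.append(dataset.samples[cov].to_numpy(dtype=float))
        names.append(cov)
    X = np.column_stack(cols)
    _check_full_rank(X, names)
    if np.linalg.cond(X) > COND_WARN:
        warnings.warn(
            f"design matrix is ill-conditioned (cond > {COND_WARN:g}); "
            "estimates are computed by QR/least-squares",
            RuntimeWarning,
            stacklevel=2,
        )
    codes, ids = pd.factorize(dataset.samples["individual_id"], sort=True)
    return DesignMatrix(X=X, columns=names, age_origin=origin), ClusterIndex(
        codes=codes, ids=list(ids)
    )


@dataclass
class OLSBatchFit:
    """Coefficients and residuals for a batch of CpGs sharing one design."""

    coef: np.ndarray  # (n_cpgs, p)
    residuals: np.ndarray  # (n_cpgs, n_obs), NaN where the row was not used
    rows_used: np.ndarray  # (n_cpgs,)
    ok: np.ndarray  # (n_cpgs,) bool — False when unfit (too few rows / rank)


def _missingness_groups(beta: np.ndarray):
    """Group CpG rows by identical missingness pattern."""
    missing = ~np.isfinite(beta)
    if not missing.any():
        yield np.arange(beta.shape[0]), np.ones(beta.shape[1], dtype=bool)
        return
    keys = {}
    for i in range(beta.shape[0]):
        keys.setdefault(missing[i].tobytes(), []).append(i)
    for key, idx in keys.items():
        rows = ~np.frombuffer(key, dtype=bool)
        yield np.asarray(idx), rows.copy()


def fit_ols_batch(beta: np.ndarray, design: DesignMatrix) -> OLSBatchFit:
    """Least-squares fit of every CpG against the shared design.

    CpGs with complete data share a single QR factorization; CpGs with
    missing values are refit on their complete rows, grouped by missingness
    pattern.  A CpG with fewer usable rows than parameters (or a
    rank-deficient row subset) is flagged unfit rather than raising.
    """
    beta = np.atleast_2d(np.asarray(beta, dtype=float))
    X = design.X
    n_cpgs, n_obs = beta.shape
    p = X.shape[1]
    if n_obs != X.shape[0]:
        raise ValidationError(
            f"beta has {n_obs} observation columns but design has {X.shape[0]} rows"
        )
    coef = np.full((n_cpgs, p), np.nan)
    resid = np.full((n_cpgs, n_obs), np.nan)
    rows_used = np.zeros(n_cpgs, dtype=int)
    ok = np.zeros(n_cpgs, dtype=bool)
    for idx, rows in _missingness_groups(beta):
        nr = int(rows.sum())
        rows_used[idx] = nr
        if nr < p:
            continue
        Xs = X[rows]
        Y = beta[np.ix_(idx, np.where(rows)[0])]  # (k, nr)
        sol, _, rank, _ = np.linalg.lstsq(Xs, Y.T, rcond=None)
        if rank < p:
            continue
        coef[idx] = sol.T
        resid[np.ix_(idx, np.where(rows)[0])] = Y - sol.T @ Xs.T
        ok[idx] = True
    return OLSBatchFit(coef=coef, residuals=resid, rows_used=rows_used, ok=ok)


def cluster_robust_variance(
    design: DesignMatrix,
    residuals: np.ndarray,
    clusters: ClusterIndex,
    correction: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sandwich covariance V per CpG.

    ``residuals`` is the (n_cpgs, n_obs) matrix from :func:`fit_ols_batch`;
    NaN entries mark rows excluded for that CpG, and both the bread
    (X'X)^-1 and the cluster count m are recomputed on each CpG's used
    rows.  With ``correction`` the meat is scaled by m/(m-1) (CR1).

    Returns ``(V, m_used, reliable)``: V has shape (n_cpgs, p, p); a CpG
    with m <= p clusters is flagged unreliable.
    """
    residuals = np.atleast_2d(np.asarray(residuals, dtype=float))
    X = design.X
    p = X.shape[1]
    n_cpgs = residuals.shape[0]
    V = np.full((n_cpgs, p, p), np.nan)
    m_used = np.zeros(n_cpgs, dtype=int)
    reliable = np.zeros(n_cpgs, dtype=bool)
    for idx, rows in _missingness_groups(residuals):
        nr = int(rows.sum())
        if nr < p:
            continue
        Xs = X[rows]
        XtX = Xs.T @ Xs
        try:
            bread = np.linalg.inv(XtX)
        except np.linalg.LinAlgError:
            continue
        codes_s = clusters.codes[rows]
        order = np.argsort(codes_s, kind="stable")
        sorted_codes = codes_s[order]
        starts = np.flatnonzero(np.r_[True, sorted_codes[1:] != sorted_codes[:-1]])
        m = len(starts)
        E = residuals[np.ix_(idx, np.where(rows)[0])][:, order]  # (k, nr)
        S = E[:, :, None] * Xs[order][None, :, :]  # (k, nr, p)
        W = np.add.reduceat(S, starts, axis=1)  # (k, m, p)
        meat = np.einsum("kjp,kjq->kpq", W, W)
        if correction and m > 1:
            meat *= m / (m - 1)
        V[idx] = bread @ meat @ bread
        m_used[idx] = m
        reliable[idx] = m > p
    return V, m_used, reliable


def wald_test(
    coef: np.ndarray,
    V: np.ndarray,
    m_used: np.ndarray,
    config: AnalysisConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-parameter Wald statistics and two-sided p-values.

    The reference distribution is the standard normal by default, or
    Student t with m - p degrees of freedom under
    ``df_method="t_clusters_minus_p"``.  Degenerate SEs follow the
    convention p = 1 for a zero estimate with zero SE (no evidence either
    way) and p = 0 for a nonzero estimate with zero SE.
    """
    coef = np.atleast_2d(coef)
    V = np.asarray(V)
    if V.ndim == 2:
        V = V[None]
    p = coef.shape[1]
    diag = np.einsum("kii->ki", V)
    se = np.sqrt(np.clip(diag, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = coef / se
    zero_se = se == 0
    with np.errstate(invalid="ignore"):
        stat = np.where(zero_se & (coef == 0), 0.0, stat)
        stat = np.where(zero_se & (coef != 0), np.sign(coef) * np.inf, stat)
    if np.any(zero_se & (coef != 0) & np.isfinite(coef)):
        warnings.warn(
            "zero standard error with nonzero estimate; p-value set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    if config.df_method == "t_clusters_minus_p":
        df = np.maximum(np.asarray(m_used, dtype=float) - p, 1.0)[:, None]
        pval = 2.0 * stats.t.sf(np.abs(stat), df)
    else:
        pval = 2.0 * stats.norm.sf(np.abs(stat))
    pval = np.where(np.isnan(stat), np.nan, pval)
    return se, stat, pval


def fit_robust_batch(
    dataset: LongitudinalDataset, config: AnalysisConfig
) -> ResultTable:
    """Fit every CpG with OLS + cluster-robust SEs; assemble a result table."""
    design, clusters = build_design(dataset, config)
    fit = fit_ols_batch(dataset.beta, design)
    V, m_used, reliable = cluster_robust_variance(
        design, fit.residuals, clusters, correction=config.small_sample_correction
    )
    se, stat, pval = wald_test(fit.coef, V, m_used, config)
    rows = []
    for i, cpg in enumerate(dataset.cpg_ids):
        if not fit.ok[i]:
            status = "unfit"
        elif not reliable[i]:
            status = "unreliable"
        else:
            status = "ok"
        for k, name in enumerate(design.columns):
            rows.append(
                {
                    "cpg_id": cpg,
                    "strategy": "robust_lm",
                    "parameter": name,
                    "estimate": fit.coef[i, k],
                    "se": se[i, k],
                    "statistic": stat[i, k],
                    "p_value": pval[i, k] if status != "unfit" else np.nan,
                    "n_obs": fit.rows_used[i],
                    "n_clusters": m_used[i],
                    "status": status,
                }
            )
    return ResultTable(pd.DataFrame(rows))
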