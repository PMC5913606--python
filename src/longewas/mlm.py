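"""Per-CpG linear mixed models (random intercept; random intercept + slope).

The model for CpG methylation y_ij of individual j at centred age x_ij is

    y_ij = (b00 + b01 z_j + u0j) + (b10 + b11 z_j + u1j) x_ij + e_ij

with (u0j, u1j) ~ N(0, Sigma_u) (unstructured 2x2; intercept-only drops
u1j) and e_ij ~ N(0, sigma_e^2).

Estimation is REML with the fixed effects and residual variance profiled
out, leaving at most three free variance parameters.  Writing
V_j = sigma_e^2 (I + Z_j G Z_j') with G = Sigma_u / sigma_e^2, G is
parameterized through a log-Cholesky factor (log-diagonal) so it stays
positive semidefinite throughout optimization; the profiled criterion

    f(theta) = (n - p) log RSS_V + sum_j log|V0_j| + log|X' V0^-1 X|

(V0_j = I + Z_j G Z_j', RSS_V the GLS residual quadratic form) is
minimized by L-BFGS-B.  Clusters sharing the same random-effects design
Z_j — all of them, in a balanced panel — share one small V0 inverse, so an
objective evaluation is a handful of dense einsums regardless of the
number of individuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .config import AnalysisConfig
from .datamodel import LongitudinalDataset, ResultTable, ValidationError
from .robust_lm import ClusterIndex, DesignMatrix, build_design

RANDOM_MODES = ("intercept", "intercept_slope")

#: bound on the log-scale Cholesky diagonal; exp(2 * floor) is the smallest
#: representable variance ratio, below which a component is "on the boundary"
LOG_DIAG_FLOOR = -7.0
LOG_DIAG_CEIL = 9.0


@dataclass
class VarianceComponents:
    """Estimated random-effect covariance and residual variance."""

    sigma_u: np.ndarray  # (q, q)
    sigma_e2: float


@dataclass
class LMMFit:
    """One converged (or flagged) mixed-model fit."""

    params: np.ndarray
    se: np.ndarray
    columns: list[str]
    cov_params: np.ndarray
    components: VarianceComponents | None
    loglik: float
    status: str  # converged | max_iter | boundary | failed
    boundary: bool
    n_obs: int
    n_clusters: int
    random: str

    @property
    def converged(self) -> bool:
        return self.status in ("converged", "boundary")


class _REMLProblem:
    """Precomputed cluster blocks for repeated fits sharing one design.

    Clusters are grouped by their random-effects design Z_j; each group
    shares the V0 inverse and log-determinant at every objective
    evaluation.  The grouping depends only on (X, Z, cluster codes), so one
    problem object serves every CpG with the same missingness pattern.
    """

    def __init__(self, X: np.ndarray, Z: np.ndarray, codes: np.ndarray):
        self.n, self.p = X.shape
        self.q = Z.shape[1]
        order = np.argsort(codes, kind="stable")
        sorted_codes = codes[order]
        starts = np.flatnonzero(np.r_[True, sorted_codes[1:] != sorted_codes[:-1]])
        bounds = np.r_[starts, len(sorted_codes)]
        self.m = len(starts)
        groups: dict[bytes, list[np.ndarray]] = {}
        for a, b in zip(bounds[:-1], bounds[1:]):
            rows = order[a:b]
            key = Z[rows].tobytes() + bytes([len(rows)])
            groups.setdefault(key, []).append(rows)
        self.blocks = []
        for members in groups.values():
            rows3 = np.stack(members)  # (k, n_g)
            Xg = X[rows3]  # (k, n_g, p)
            self.blocks.append(
                {
                    "rows": rows3,
                    "X": Xg,
                    "Z": Z[members[0]],  # (n_g, q)
                    # sufficient statistic sum_k X_k (x) X_k: objective
                    # evaluations then cost O(n_g^2 p^2) independent of k
                    "XX": np.einsum("knp,kmq->nmpq", Xg, Xg),
                }
            )
        # slope variance is identifiable only if some cluster sees >1 distinct x
        self.slope_identifiable = any(
            len(np.unique(b["Z"][:, -1])) > 1 for b in self.blocks
        ) if self.q > 1 else True

    def _gmat(self, theta: np.ndarray) -> np.ndarray:
        if self.q == 1:
            return np.array([[np.exp(2.0 * theta[0])]])
        L = np.array([[np.exp(theta[0]), 0.0], [theta[1], np.exp(theta[2])]])
        return L @ L.T

    def prepare(self, y: np.ndarray) -> list[dict]:
        """Outcome-dependent sufficient statistics, computed once per fit."""
        stats_blocks = []
        for blk in self.blocks:
            Yg = y[blk["rows"]]  # (k, n_g)
            stats_blocks.append(
                {
                    "yX": np.einsum("kn,kmp->nmp", Yg, blk["X"]),
                    "yy": Yg.T @ Yg,  # (n_g, n_g)
                }
            )
        return stats_blocks

    def _profile(self, theta: np.ndarray, stats_blocks: list[dict]):
        """GLS profile at variance ratio G(theta).

        Returns (beta, RSS_V, A = X'V0^-1 X, log|A|, sum_j log|V0_j|).
        """
        G = self._gmat(theta)
        A = np.zeros((self.p, self.p))
        b = np.zeros(self.p)
        yy_v = 0.0
        logdet_v = 0.0
        for blk, st in zip(self.blocks, stats_blocks):
            Z = blk["Z"]
            ng = Z.shape[0]
            V0 = np.eye(ng) + Z @ G @ Z.T
            c, low = linalg.cho_factor(V0, lower=True)
            logdet_v += 2.0 * np.sum(np.log(np.diag(c))) * blk["rows"].shape[0]
            Vinv = linalg.cho_solve((c, low), np.eye(ng))
            A += np.einsum("nm,nmpq->pq", Vinv, blk["XX"])
            b += np.einsum("nm,nmp->p", Vinv, st["yX"])
            yy_v += float(np.sum(Vinv * st["yy"]))
        sign, logdet_a = np.linalg.slogdet(A)
        if sign <= 0:
            raise np.linalg.LinAlgError("X'V^-1X not positive definite")
        beta = np.linalg.solve(A, b)
        rss = yy_v - float(b @ beta)
        return beta, rss, A, logdet_a, logdet_v

    def neg2reml(self, theta: np.ndarray, stats_blocks: list[dict]) -> float:
        """Profiled -2 restricted log-likelihood, up to an additive constant."""
        try:
            _, rss, _, logdet_a, logdet_v = self._profile(theta, stats_blocks)
        except (np.linalg.LinAlgError, linalg.LinAlgError):
            return 1e12
        if not np.isfinite(rss) or rss <= 0:
            return 1e12
        return (self.n - self.p) * np.log(rss) + logdet_v + logdet_a

    def fit(
        self,
        y: np.ndarray,
        max_iter: int = 200,
        tol: float = 1e-8,
        theta0: np.ndarray | None = None,
    ):
        stats_blocks = self.prepare(y)
        if self.q == 1:
            x0 = np.zeros(1) if theta0 is None else theta0
            bounds = [(LOG_DIAG_FLOOR, LOG_DIAG_CEIL)]
        else:
            x0 = np.zeros(3) if theta0 is None else theta0
            bounds = [
                (LOG_DIAG_FLOOR, LOG_DIAG_CEIL),
                (-1e3, 1e3),
                (LOG_DIAG_FLOOR, LOG_DIAG_CEIL),
            ]
        res = optimize.minimize(
            self.neg2reml,
            x0,
            args=(stats_blocks,),
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-6, "eps": 1e-6},
        )
        theta = res.x
        beta, rss, A, logdet_a, logdet_v = self._profile(theta, stats_blocks)
        dof = self.n - self.p
        sigma_e2 = rss / dof
        G = self._gmat(theta)
        sigma_u = sigma_e2 * G
        cov_params = sigma_e2 * np.linalg.inv(A)
        # full REML log-likelihood (natural-log scale, all constants included)
        loglik = -0.5 * (
            dof * np.log(sigma_e2) + logdet_v + logdet_a + dof + dof * np.log(2 * np.pi)
        )
        log_diags = theta[[0]] if self.q == 1 else theta[[0, 2]]
        boundary = bool(np.any(log_diags <= LOG_DIAG_FLOOR + 1e-6))
        # line searches can stall from finite-difference noise after the
        # criterion has flattened; a small projected gradient still counts
        # as a stationary point
        grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.inf
        if boundary:
            status = "boundary"
        elif res.success or grad_norm <= 1e-3:
            status = "converged"
        else:
            status = "max_iter"
        return beta, cov_params, VarianceComponents(sigma_u, sigma_e2), loglik, status, boundary


def _build_problem(
    design: DesignMatrix, clusters: ClusterIndex, keep: np.ndarray, random: str
) -> _REMLProblem:
    X = design.X[keep]
    codes = clusters.codes[keep]
    age_col = design.columns.index("age")
    if random == "intercept":
        Z = np.ones((X.shape[0], 1))
    else:
        Z = np.column_stack([np.ones(X.shape[0]), X[:, age_col]])
    return _REMLProblem(X, Z, codes)


def fit_lmm(
    y: np.ndarray,
    design: DesignMatrix,
    clusters: ClusterIndex,
    random: str = "intercept_slope",
    max_iter: int = 200,
    tol: float = 1e-8,
    _problem: _REMLProblem | None = None,
) -> LMMFit:
    """REML fit of one CpG's mixed model.

    ``random`` selects the random-effects structure: ``"intercept"`` (one
    variance) or ``"intercept_slope"`` (unstructured 2x2 covariance of the
    intercept and age-slope deviations).  Boundary estimates (a variance
    driven to zero) are returned with the boundary flag set; non-convergence
    returns the best iterate with status ``max_iter``.
    """
    if random not in RANDOM_MODES:
        raise ValidationError(f"unknown random mode {random!r}; valid: {RANDOM_MODES}")
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(y)
    X = design.X[keep]
    codes = clusters.codes[keep]
    yk = y[keep]
    n, p = X.shape
    failed = LMMFit(
        params=np.full(p, np.nan),
        se=np.full(p, np.nan),
        columns=list(design.columns),
        cov_params=np.full((p, p), np.nan),
        components=None,
        loglik=np.nan,
        status="failed",
        boundary=False,
        n_obs=n,
        n_clusters=len(np.unique(codes)),
        random=random,
    )
    if len(np.unique(codes)) < 2:
        raise ValidationError("mixed model requires at least 2 clusters")
    if n <= p or np.ptp(yk) == 0:
        return failed
    problem = _problem if _problem is not None else _build_problem(
        design, clusters, keep, random
    )
    if random == "intercept_slope" and not problem.slope_identifiable:
        return failed
    try:
        params, cov_params, comps, loglik, status, boundary = problem.fit(
            yk, max_iter=max_iter, tol=tol
        )
    except (np.linalg.LinAlgError, linalg.LinAlgError, ValueError):
        return failed
    return LMMFit(
        params=params,
        se=np.sqrt(np.clip(np.diag(cov_params), 0.0, None)),
        columns=list(design.columns),
        cov_params=cov_params,
        components=comps,
        loglik=loglik,
        status=status,
        boundary=boundary,
        n_obs=n,
        n_clusters=problem.m,
        random=random,
    )


def lmm_wald(fit: LMMFit, config: AnalysisConfig) -> np.ndarray:
    """Two-sided Wald p-values (standard-normal reference) per fixed effect.

    Returns NaN for a failed fit; the same inference rule as the
    cluster-robust route, so identical estimate/SE pairs give identical
    p-values.
    """
    if fit.status == "failed":
        return np.full(len(fit.columns), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = fit.params / fit.se
    z = np.where((fit.se == 0) & (fit.params == 0), 0.0, z)
    z = np.where((fit.se == 0) & (fit.params != 0), np.inf, z)
    return 2.0 * stats.norm.sf(np.abs(z))


def _fit_chunk(
    dataset: LongitudinalDataset,
    config: AnalysisConfig,
    random: str,
    indices: np.ndarray,
) -> list[dict]:
    design, clusters = build_design(dataset, config)
    strategy = "lmm_intercept" if random == "intercept" else "lmm_intercept_slope"
    problems: dict[bytes, _REMLProblem] = {}
    rows = []
    for i in indices:
        cpg = dataset.cpg_ids[i]
        keep = np.isfinite(dataset.beta[i])
        key = keep.tobytes()
        if key not in problems:
            problems[key] = _build_problem(design, clusters, keep, random)
        fit = fit_lmm(
            dataset.beta[i], design, clusters, random=random, _problem=problems[key]
        )
        pvals = lmm_wald(fit, config)
        for k, name in enumerate(design.columns):
            rows.append(
                {
                    "cpg_id": cpg,
                    "strategy": strategy,
                    "parameter": name,
                    "estimate": fit.params[k],
                    "se": fit.se[k],
                    "statistic": (
                        fit.params[k] / fit.se[k] if fit.se[k] > 0 else np.nan
                    ),
                    "p_value": pvals[k],
                    "n_obs": fit.n_obs,
                    "n_clusters": fit.n_clusters,
                    "status": fit.status,
                }
            )
    return rows


def fit_lmm_batch(
    dataset: LongitudinalDataset,
    config: AnalysisConfig,
    random: str = "intercept_slope",
    n_threads: int = 1,
) -> ResultTable:
    """Fit the mixed model to every CpG; failures are isolated per CpG.

    CpGs sharing a missingness pattern share the precomputed cluster
    blocks, so the balanced complete-data case pays the grouping cost once.
    Every CpG is optimized from the same fixed start and fits are
    independent, so results do not depend on ``n_threads`` or on execution
    order.
    """
    if random not in RANDOM_MODES:
        raise ValidationError(f"unknown random mode {random!r}; valid: {RANDOM_MODES}")
    build_design(dataset, config)  # fail fast on design problems
    all_idx = np.arange(dataset.n_cpgs)
    if n_threads <= 1 or dataset.n_cpgs < 2 * n_threads:
        rows = _fit_chunk(dataset, config, random, all_idx)
    else:
        from joblib import Parallel, delayed

        chunks = np.array_split(all_idx, n_threads)
        results = Parallel(n_jobs=n_threads)(
            delayed(_fit_chunk)(dataset, config, random, c) for c in chunks
        )
        rows = [row for chunk_rows in results for row in chunk_rows]
    return ResultTable(pd.DataFrame(rows))
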