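"""Cross-sectional EWAS per time-point and hit-selection strategies.

Three cross-sectional selection rules are compared with the longitudinal
models: a CpG is a hit when its exposure p-value falls below the threshold
at the first time-point only (``baseline``), at one or more time-points
(``any_timepoint``), or at every time-point (``all_timepoints``).  For the
longitudinal models a CpG is a hit when any exposure-related parameter
(baseline effect or age interaction) is below the threshold.

Observations at a single time-point come from distinct individuals, so the
per-time-point regressions use classical OLS standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .datamodel import (
    EXPOSURE_PARAMETERS,
    LongitudinalDataset,
    ResultTable,
    ValidationError,
)
from .robust_lm import DesignMatrix, _missingness_groups

EWAS_STRATEGIES = ("baseline", "any_timepoint", "all_timepoints")
LONGITUDINAL_STRATEGIES = ("lmm_intercept", "lmm_intercept_slope", "robust_lm")


@dataclass
class StrategyHits:
    """Hit set produced by one selection strategy."""

    strategy: str
    hits: frozenset
    triggers: pd.DataFrame = field(default_factory=pd.DataFrame)
    n_excluded: int = 0


def available_timepoints(
    dataset: LongitudinalDataset, tolerance: float = 0.5
) -> list[float]:
    """Nominal time-points: unique ages merged within ``tolerance`` years."""
    ages = np.sort(np.unique(dataset.ages))
    groups: list[list[float]] = [[float(ages[0])]]
    for a in ages[1:]:
        if a - groups[-1][-1] <= tolerance:
            groups[-1].append(float(a))
        else:
            groups.append([float(a)])
    return [float(np.mean(g)) for g in groups]


def ewas_at_timepoint(
    dataset: LongitudinalDataset,
    timepoint: float,
    config: AnalysisConfig,
) -> pd.DataFrame:
    """Cross-sectional EWAS restricted to observations near one age.

    Per CpG, OLS of methylation on exposure (+ covariates) over the
    observations within ``config.timepoint_tolerance`` years of
    ``timepoint``; classical SEs and two-sided t p-values for the exposure
    coefficient.
    """
    ages = dataset.ages
    mask = np.abs(ages - timepoint) <= config.timepoint_tolerance
    if not mask.any():
        raise ValidationError(
            f"no observations at time-point {timepoint}; available time-points: "
            f"{available_timepoints(dataset, config.timepoint_tolerance)}"
        )
    z = dataset.exposure[mask]
    for grp in (0, 1):
        if (z == grp).sum() < 2:
            raise ValidationError(
                f"fewer than 2 observations with exposure={grp} at time-point "
                f"{timepoint}"
            )
    cols = [np.ones(mask.sum()), z]
    names = ["intercept", "exposure"]
    for cov in config.covariates:
        if cov not in dataset.samples.columns:
            raise ValidationError(
                f"covariate {cov!r} named in config is absent from the sample sheet"
            )
        cols.append(dataset.samples.loc[mask, cov].to_numpy(dtype=float))
        names.append(cov)
    X = np.column_stack(cols)
    beta = dataset.beta[:, mask]
    p = X.shape[1]
    zi = names.index("exposure")

    est = np.full(dataset.n_cpgs, np.nan)
    se = np.full(dataset.n_cpgs, np.nan)
    pval = np.full(dataset.n_cpgs, np.nan)
    nused = np.zeros(dataset.n_cpgs, dtype=int)
    for idx, rows in _missingness_groups(beta):
        nr = int(rows.sum())
        nused[idx] = nr
        if nr <= p:
            continue
        Xs = X[rows]
        Y = beta[np.ix_(idx, np.where(rows)[0])]
        sol, _, rank, _ = np.linalg.lstsq(Xs, Y.T, rcond=None)
        if rank < p:
            continue
        resid = Y - sol.T @ Xs.T
        s2 = np.sum(resid**2, axis=1) / (nr - p)
        xtx_inv = np.linalg.inv(Xs.T @ Xs)
        est[idx] = sol[zi]
        se[idx] = np.sqrt(s2 * xtx_inv[zi, zi])
        with np.errstate(divide="ignore", invalid="ignore"):
            t = sol[zi] / se[idx]
        pval[idx] = 2.0 * stats.t.sf(np.abs(t), nr - p)
    return pd.DataFrame(
        {
            "cpg_id": dataset.cpg_ids,
            "timepoint": timepoint,
            "estimate": est,
            "se": se,
            "p_value": pval,
            "n": nused,
        }
    )


def cross_sectional_ewas(
    dataset: LongitudinalDataset, config: AnalysisConfig
) -> pd.DataFrame:
    """Run :func:`ewas_at_timepoint` at every available time-point."""
    frames = [
        ewas_at_timepoint(dataset, t, config)
        for t in available_timepoints(dataset, config.timepoint_tolerance)
    ]
    return pd.concat(frames, ignore_index=True)


def select_hits(
    results: pd.DataFrame | ResultTable,
    strategy: str,
    config: AnalysisConfig,
) -> StrategyHits:
    """Classify CpGs as hits under one strategy.

    ``results`` is a per-time-point EWAS table (from
    :func:`cross_sectional_ewas`) for the cross-sectional strategies, or a
    :class:`ResultTable` for the longitudinal ones.  CpGs with missing
    p-values are excluded and counted.
    """
    tau = config.significance_threshold
    if strategy in EWAS_STRATEGIES:
        if isinstance(results, ResultTable):
            raise ValidationError(
                f"strategy {strategy!r} needs a per-time-point EWAS table"
            )
        wide = results.pivot(index="cpg_id", columns="timepoint", values="p_value")
        complete = wide.dropna()
        n_excluded = len(wide) - len(complete)
        timepoints = sorted(wide.columns)
        if strategy == "baseline":
            pmin = complete[timepoints[0]]
            hit = pmin < tau
            trig = pd.DataFrame(
                {"cpg_id": complete.index[hit], "trigger": f"t={timepoints[0]}"}
            )
        elif strategy == "any_timepoint":
            hit = complete.min(axis=1) < tau
            best = complete.idxmin(axis=1)
            trig = pd.DataFrame(
                {
                    "cpg_id": complete.index[hit],
                    "trigger": [f"t={t}" for t in best[hit]],
                }
            )
        else:  # all_timepoints
            hit = complete.max(axis=1) < tau
            trig = pd.DataFrame(
                {"cpg_id": complete.index[hit], "trigger": "all time-points"}
            )
        return StrategyHits(
            strategy=strategy,
            hits=frozenset(complete.index[hit]),
            triggers=trig.reset_index(drop=True),
            n_excluded=n_excluded,
        )
    if strategy in LONGITUDINAL_STRATEGIES:
        table = results.table if isinstance(results, ResultTable) else results
        sub = table[table["parameter"].isin(EXPOSURE_PARAMETERS)]
        wide = sub.pivot(index="cpg_id", columns="parameter", values="p_value")
        complete = wide.dropna()
        n_excluded = len(wide) - len(complete)
        hit = complete.min(axis=1) < tau
        best = complete.idxmin(axis=1)
        trig = pd.DataFrame(
            {"cpg_id": complete.index[hit], "trigger": best[hit].to_numpy()}
        )
        return StrategyHits(
            strategy=strategy,
            hits=frozenset(complete.index[hit]),
            triggers=trig.reset_index(drop=True),
            n_excluded=n_excluded,
        )
    raise ValidationError(f"unknown strategy {strategy!r}")
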