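"""Power, Type I error and relative-bias comparison across strategies.

The harness streams simulation replicates, fits every requested strategy,
classifies hits at the configured threshold, and aggregates:

power
    per (strategy, scenario), the fraction of replicates in which that
    scenario's causal CpG was a hit;
Type I error
    per strategy, the fraction of (replicate x null CpG) tests flagged —
    the denominator pools the null CpGs across replicates;
relative bias
    per (model, scenario, exposure parameter), summaries of
    (estimate - truth) / truth over replicates, reported as NA when the
    true parameter is zero.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .datamodel import EXPOSURE_PARAMETERS, ResultTable, ValidationError
from .ewas import EWAS_STRATEGIES, StrategyHits, cross_sectional_ewas, select_hits
from .mlm import fit_lmm_batch
from .robust_lm import fit_robust_batch
from .simulate import SimulationConfig, simulate_dataset

ALL_STRATEGIES = (
    "baseline",
    "any_timepoint",
    "all_timepoints",
    "lmm_intercept",
    "lmm_intercept_slope",
    "robust_lm",
)

#: result-table parameter name for each trajectory fixed effect
PARAMETER_LABELS = {"exposure": "beta01", "exposure:age": "beta11"}


@dataclass
class PowerTable:
    """Power per (strategy, scenario) and pooled Type I error per strategy."""

    power: pd.DataFrame  # columns: strategy, scenario, power, mc_se, n_replicates
    type1: pd.DataFrame  # columns: strategy, type1, mc_se, n_tests
    n_replicates: int


@dataclass
class EvaluationReport:
    power_table: PowerTable
    bias_table: pd.DataFrame
    equivalence: pd.DataFrame
    n_replicates: int
    n_failed: int
    failures: list = field(default_factory=list)


def _mc_se(phat: float, n: int) -> float:
    return float(np.sqrt(phat * (1 - phat) / n)) if n > 0 else np.nan


def compute_power(
    hits_stream: list[dict[str, StrategyHits]],
    truth_tables: list[pd.DataFrame],
) -> PowerTable:
    """Aggregate a stream of per-replicate hit sets into power and Type I error."""
    if not hits_stream:
        raise ValidationError("compute_power needs at least one replicate")
    if len(hits_stream) != len(truth_tables):
        raise ValidationError("hits stream and truth tables differ in length")
    n_rep = len(hits_stream)
    strategies = list(hits_stream[0].keys())
    scenarios = sorted(
        {s for t in truth_tables for s in t["scenario"].unique() if s != "null"}
    )
    power_rows = []
    type1_rows = []
    for strat in strategies:
        for sc in scenarios:
            count = 0
            for hits, truth in zip(hits_stream, truth_tables):
                causal = truth.loc[truth["scenario"] == sc, "cpg_id"]
                if len(causal) and causal.iloc[0] in hits[strat].hits:
                    count += 1
            phat = count / n_rep
            power_rows.append(
                {
                    "strategy": strat,
                    "scenario": sc,
                    "power": phat,
                    "mc_se": _mc_se(phat, n_rep),
                    "n_replicates": n_rep,
                }
            )
        flagged = 0
        n_tests = 0
        for hits, truth in zip(hits_stream, truth_tables):
            nulls = set(truth.loc[truth["scenario"] == "null", "cpg_id"])
            n_tests += len(nulls)
            flagged += len(nulls & hits[strat].hits)
        t1 = flagged / n_tests if n_tests else np.nan
        type1_rows.append(
            {
                "strategy": strat,
                "type1": t1,
                "mc_se": _mc_se(t1, n_tests),
                "n_tests": n_tests,
            }
        )
    return PowerTable(
        power=pd.DataFrame(power_rows),
        type1=pd.DataFrame(type1_rows),
        n_replicates=n_rep,
    )


def relative_bias(
    estimates: pd.DataFrame,
    quantiles: tuple[float, float] = (0.025, 0.975),
) -> pd.DataFrame:
    """Summarize relative bias (b_hat - b) / b of the exposure parameters.

    ``estimates`` is long form with columns model, scenario, parameter,
    estimate, se, truth (one row per replicate x causal CpG x parameter).
    Cells whose true parameter is zero report NA bias (the relative scale
    is undefined) but keep the SE summaries.
    """
    required = {"model", "scenario", "parameter", "estimate", "se", "truth"}
    missing = required - set(estimates.columns)
    if missing:
        raise ValidationError(f"estimates table missing column(s): {sorted(missing)}")
    rows = []
    for (model, sc, par), grp in estimates.groupby(
        ["model", "scenario", "parameter"], sort=True
    ):
        truth = grp["truth"].to_numpy(dtype=float)
        est = grp["estimate"].to_numpy(dtype=float)
        se = grp["se"].to_numpy(dtype=float)
        row = {
            "model": model,
            "scenario": sc,
            "parameter": par,
            "n": len(grp),
            "mean_se": float(np.nanmean(se)),
            "sd_se": float(np.nanstd(se, ddof=1)) if len(se) > 1 else np.nan,
        }
        if np.all(truth == 0):
            row.update(
                mean_rel_bias=np.nan,
                sd_rel_bias=np.nan,
                q_lower=np.nan,
                q_upper=np.nan,
            )
        else:
            rel = (est - truth) / truth
            rel = rel[np.isfinite(rel)]
            row.update(
                mean_rel_bias=float(np.mean(rel)),
                sd_rel_bias=float(np.std(rel, ddof=1)) if len(rel) > 1 else np.nan,
                q_lower=float(np.quantile(rel, quantiles[0])),
                q_upper=float(np.quantile(rel, quantiles[1])),
            )
        rows.append(row)
    cols = [
        "model",
        "scenario",
        "parameter",
        "mean_rel_bias",
        "sd_rel_bias",
        "q_lower",
        "q_upper",
        "mean_se",
        "sd_se",
        "n",
    ]
    return pd.DataFrame(rows)[cols]


def _collect_estimates(
    result: ResultTable, truth: pd.DataFrame, model: str, replicate: int
) -> pd.DataFrame:
    causal = truth[truth["scenario"] != "null"]
    sub = result.table[
        result.table["cpg_id"].isin(causal["cpg_id"])
        & result.table["parameter"].isin(EXPOSURE_PARAMETERS)
    ].copy()
    merged = sub.merge(
        causal[["cpg_id", "scenario", "beta01", "beta11"]], on="cpg_id"
    )
    merged["truth"] = np.where(
        merged["parameter"] == "exposure", merged["beta01"], merged["beta11"]
    )
    merged["model"] = model
    merged["replicate"] = replicate
    return merged[
        ["replicate", "cpg_id", "scenario", "model", "parameter", "estimate", "se", "truth"]
    ]


def compare_strategies(
    sim_config: SimulationConfig,
    analysis_config: AnalysisConfig,
    n_replicates: int = 100,
    seed: int | None = None,
    strategies: tuple[str, ...] = ALL_STRATEGIES,
) -> EvaluationReport:
    """Run the full simulate -> fit -> classify -> aggregate loop.

    Per replicate, each requested strategy is fitted and hits classified at
    the configured threshold.  Per-replicate failures are isolated; the run
    aborts only if more than 10% of replicates fail.  The equivalence
    report tabulates per-CpG estimate and SE deltas between the
    cluster-robust regression and the random-intercept-and-slope mixed
    model on the causal CpGs.
    """
    unknown = set(strategies) - set(ALL_STRATEGIES)
    if unknown:
        raise ValidationError(f"unknown strategies: {sorted(unknown)}")
    if seed is not None:
        sim_config = dataclasses.replace(sim_config, seed=seed)
    hits_stream: list[dict[str, StrategyHits]] = []
    truths: list[pd.DataFrame] = []
    estimate_frames: list[pd.DataFrame] = []
    failures: list[tuple[int, str]] = []
    want_cs = any(s in EWAS_STRATEGIES for s in strategies)
    for r in range(n_replicates):
        try:
            dataset, truth = simulate_dataset(sim_config, replicate_index=r)
            hits: dict[str, StrategyHits] = {}
            if want_cs:
                cs = cross_sectional_ewas(dataset, analysis_config)
                for s in EWAS_STRATEGIES:
                    if s in strategies:
                        hits[s] = select_hits(cs, s, analysis_config)
            if "robust_lm" in strategies:
                res = fit_robust_batch(dataset, analysis_config)
                hits["robust_lm"] = select_hits(res, "robust_lm", analysis_config)
                estimate_frames.append(_collect_estimates(res, truth, "robust_lm", r))
            if "lmm_intercept" in strategies:
                res = fit_lmm_batch(dataset, analysis_config, random="intercept")
                hits["lmm_intercept"] = select_hits(
                    res, "lmm_intercept", analysis_config
                )
            if "lmm_intercept_slope" in strategies:
                res = fit_lmm_batch(dataset, analysis_config, random="intercept_slope")
                hits["lmm_intercept_slope"] = select_hits(
                    res, "lmm_intercept_slope", analysis_config
                )
                estimate_frames.append(
                    _collect_estimates(res, truth, "lmm_intercept_slope", r)
                )
        except Exception as exc:  # noqa: BLE001 — isolate per-replicate failures
            failures.append((r, repr(exc)))
            if len(failures) > 0.1 * n_replicates:
                raise RuntimeError(
                    f"more than 10% of replicates failed; first failures: "
                    f"{failures[:3]}"
                ) from exc
            continue
        hits_stream.append(hits)
        truths.append(truth)

    power_table = compute_power(hits_stream, truths)
    estimates = (
        pd.concat(estimate_frames, ignore_index=True)
        if estimate_frames
        else pd.DataFrame(
            columns=["replicate", "cpg_id", "scenario", "model", "parameter",
                     "estimate", "se", "truth"]
        )
    )
    bias_table = (
        relative_bias(estimates) if len(estimates) else pd.DataFrame()
    )
    equivalence = _equivalence_report(estimates)
    return EvaluationReport(
        power_table=power_table,
        bias_table=bias_table,
        equivalence=equivalence,
        n_replicates=len(hits_stream),
        n_failed=len(failures),
        failures=failures,
    )


def _equivalence_report(estimates: pd.DataFrame) -> pd.DataFrame:
    """Per-parameter agreement between the two longitudinal models."""
    models = set(estimates["model"].unique()) if len(estimates) else set()
    if not {"robust_lm", "lmm_intercept_slope"} <= models:
        return pd.DataFrame()
    wide = estimates.pivot_table(
        index=["replicate", "cpg_id", "scenario", "parameter"],
        columns="model",
        values=["estimate", "se"],
    )
    rows = []
    for par, grp in wide.groupby(level="parameter"):
        a = grp[("estimate", "robust_lm")].to_numpy()
        b = grp[("estimate", "lmm_intercept_slope")].to_numpy()
        sa = grp[("se", "robust_lm")].to_numpy()
        sb = grp[("se", "lmm_intercept_slope")].to_numpy()
        keep = np.isfinite(a) & np.isfinite(b)
        rows.append(
            {
                "parameter": par,
                "n": int(keep.sum()),
                "estimate_correlation": (
                    float(np.corrcoef(a[keep], b[keep])[0, 1]) if keep.sum() > 2 else np.nan
                ),
                "mean_abs_estimate_diff": float(np.mean(np.abs(a[keep] - b[keep]))),
                "mean_min_se": float(np.mean(np.minimum(sa[keep], sb[keep]))),
                "mean_se_robust": float(np.mean(sa[keep])),
                "mean_se_lmm": float(np.mean(sb[keep])),
            }
        )
    return pd.DataFrame(rows)
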