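"""Simulation of longitudinal methylation trajectories.

The generative model for each CpG is a linear mixed model with a random
intercept and random age slope per individual:

    y_ij = (b00 + b01 z_j + u0j) + (b10 + b11 z_j + u1j) x_ij + e_ij

with (u0j, u1j) ~ N(0, Sigma_u), e_ij ~ N(0, sigma_e^2), z_j a binary
individual-level exposure and x_ij the age at measurement centred at the
first time-point.  Six causal-effect patterns describe how an exposure can
shape a trajectory (constant offset, diverging, converging, with or without
an underlying age trend); the remaining CpGs are null (b01 = b11 = 0).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import LongitudinalDataset, ValidationError

SCENARIO_LABELS = ("i", "ii", "iii", "iv", "v", "vi")


@dataclass(frozen=True)
class ScenarioSpec:
    """One causal-effect pattern, as a template for the fixed effects.

    The six patterns:

    i    constant exposure effect, no age trend        (b01 != 0, b10 = b11 = 0)
    ii   diverging from a common baseline, flat
         unexposed trajectory                          (b01 = 0, b10 = 0, b11 != 0)
    iii  diverging from a common baseline on top of
         an age trend                                  (b01 = 0, b10 != 0, b11 != 0)
    iv   constant exposure effect plus an age trend    (b01 != 0, b10 != 0, b11 = 0)
    v    baseline effect that diverges further with
         age                                           (b01 != 0, b11 != 0, same sign)
    vi   baseline effect that converges with age       (b01 != 0, b11 != 0, opposite
                                                        sign, not crossing zero)
    """

    label: str
    beta01: float
    beta10: float
    beta11: float

    def validate(self, age_span: float) -> None:
        lab, b01, b10, b11 = self.label, self.beta01, self.beta10, self.beta11
        if lab not in SCENARIO_LABELS:
            raise ValidationError(f"unknown scenario label {lab!r}")
        ok = {
            "i": b01 != 0 and b10 == 0 and b11 == 0,
            "ii": b01 == 0 and b10 == 0 and b11 != 0,
            "iii": b01 == 0 and b10 != 0 and b11 != 0,
            "iv": b01 != 0 and b10 != 0 and b11 == 0,
            "v": b01 != 0 and b11 != 0 and np.sign(b11) == np.sign(b01),
            "vi": b01 != 0
            and b11 != 0
            and np.sign(b11) == -np.sign(b01)
            and abs(b11) * age_span <= abs(b01),
        }[lab]
        if not ok:
            raise ValidationError(
                f"effect pattern (b01={b01}, b10={b10}, b11={b11}) does not match "
                f"scenario ({lab})"
            )


def default_scenarios() -> tuple[ScenarioSpec, ...]:
    """Default effect sizes for the six patterns.

    Baseline offsets of 2 percentage points of methylation and slope
    offsets of 0.4 percentage points per year give baseline and interaction
    Wald statistics in the 5-6 range at the default cohort size, i.e.
    power against the epigenome-wide threshold that is neither negligible
    nor saturated.  Scenario (vi) halves the baseline gap by age 18.
    """
    return (
        ScenarioSpec("i", beta01=0.02, beta10=0.0, beta11=0.0),
        ScenarioSpec("ii", beta01=0.0, beta10=0.0, beta11=0.004),
        ScenarioSpec("iii", beta01=0.0, beta10=0.002, beta11=0.004),
        ScenarioSpec("iv", beta01=0.02, beta10=0.002, beta11=0.0),
        ScenarioSpec("v", beta01=0.02, beta10=0.002, beta11=0.004),
        ScenarioSpec("vi", beta01=0.02, beta10=0.002, beta11=-0.00125),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Study design and generative parameters for one simulation stream.

    Defaults describe the primary design: 464 individuals each measured at
    5 equally spaced ages from 10 to 18 years, 100 CpGs of which 6 carry an
    exposure effect (one per scenario), exposure prevalence 0.5.
    """

    n_individuals: int = 464
    n_cpgs: int = 100
    repeats: int = 5
    age_min: float = 10.0
    age_max: float = 18.0
    prevalence: float = 0.5
    scenarios: tuple[ScenarioSpec, ...] = field(default_factory=default_scenarios)
    sd_u0: float = 0.035
    sd_u1: float = 0.008
    corr_u: float = -0.3
    sigma_e: float = 0.01
    beta00_range: tuple[float, float] = (0.2, 0.8)
    clip_unit_interval: bool = False
    seed: int = 0
    n_replicates: int = 1000

    def __post_init__(self) -> None:
        if self.repeats < 2:
            raise ValidationError("repeats must be >= 2")
        if self.age_max <= self.age_min:
            raise ValidationError("age_max must exceed age_min")
        if not (0.0 < self.prevalence < 1.0):
            raise ValidationError("prevalence must lie in (0, 1)")
        if self.n_causal > self.n_cpgs:
            raise ValidationError("more causal scenarios than CpGs")
        if not (-1.0 < self.corr_u < 1.0):
            raise ValidationError("corr_u must lie in (-1, 1)")
        if self.sigma_e <= 0:
            raise ValidationError("sigma_e must be > 0")
        if self.sd_u0 < 0 or self.sd_u1 < 0:
            raise ValidationError("random-effect SDs must be >= 0")
        for sc in self.scenarios:
            sc.validate(self.age_span)

    # -- derived design quantities ----------------------------------------

    @property
    def n_causal(self) -> int:
        return len(self.scenarios)

    @property
    def age_span(self) -> float:
        return self.age_max - self.age_min

    @property
    def ages(self) -> np.ndarray:
        """Equally spaced measurement ages (strictly increasing)."""
        return np.linspace(self.age_min, self.age_max, self.repeats)

    @property
    def sigma_u(self) -> np.ndarray:
        """2x2 covariance of the (intercept, slope) random effects."""
        cov = self.corr_u * self.sd_u0 * self.sd_u1
        return np.array([[self.sd_u0**2, cov], [cov, self.sd_u1**2]])

    @classmethod
    def from_mapping(cls, mapping: dict) -> "SimulationConfig":
        mapping = dict(mapping)
        if "scenarios" in mapping and mapping["scenarios"] is not None:
            mapping["scenarios"] = tuple(
                ScenarioSpec(**sc) if isinstance(sc, dict) else sc
                for sc in mapping["scenarios"]
            )
        if "beta00_range" in mapping and mapping["beta00_range"] is not None:
            mapping["beta00_range"] = tuple(mapping["beta00_range"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValidationError(
                f"unknown key(s) in 'simulation' config section: {sorted(unknown)}"
            )
        return cls(**mapping)


def _psd_sqrt(S: np.ndarray) -> np.ndarray:
    """Matrix square root of a PSD covariance; tolerates singular S."""
    try:
        return np.linalg.cholesky(S)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(S)
        return v * np.sqrt(np.clip(w, 0.0, None))


def replicate_rng(config: SimulationConfig, replicate_index: int) -> np.random.Generator:
    """Deterministic, non-overlapping random stream for one replicate.

    Streams are derived from the master seed with the replicate index as a
    spawn key, so replicates can be generated in any order (or in parallel)
    without changing any draw.
    """
    ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(replicate_index,))
    return np.random.default_rng(ss)


def simulate_individuals(
    config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw the individual table: id, binary exposure, and the shared age grid.

    Every individual is observed at every configured age (balanced panel).
    If a draw leaves one exposure group empty the exposure vector is
    redrawn (up to 100 attempts) so downstream designs are full rank.
    """
    m = config.n_individuals
    for _ in range(100):
        exposure = (rng.random(m) < config.prevalence).astype(int)
        if 0 < exposure.sum() < m:
            break
    else:
        raise ValidationError(
            f"could not draw a non-degenerate exposure split with prevalence "
            f"{config.prevalence} and n={m}"
        )
    width = max(4, len(str(m)))
    return pd.DataFrame(
        {
            "individual_id": [f"id{j:0{width}d}" for j in range(m)],
            "exposure": exposure,
        }
    )


def simulate_cpg(
    individuals: pd.DataFrame,
    scenario: ScenarioSpec | None,
    config: SimulationConfig,
    rng: np.random.Generator,
    beta00: float = 0.5,
    beta10_null: float = 0.0,
) -> np.ndarray:
    """Simulate one CpG's trajectories for all individuals.

    Returns values ordered by individual then age (matching the observation
    order produced by :func:`simulate_dataset`).  ``scenario=None`` yields a
    null CpG (b01 = b11 = 0) with age trend ``beta10_null``.
    """
    m = len(individuals)
    r = config.repeats
    x = config.ages - config.age_min  # centred age, shape (r,)
    z = individuals["exposure"].to_numpy(dtype=float)

    if scenario is None:
        b01, b10, b11 = 0.0, beta10_null, 0.0
    else:
        b01, b10, b11 = scenario.beta01, scenario.beta10, scenario.beta11

    u = rng.standard_normal((m, 2)) @ _psd_sqrt(config.sigma_u).T
    eps = rng.normal(0.0, config.sigma_e, size=(m, r))

    intercept = beta00 + b01 * z + u[:, 0]  # (m,)
    slope = b10 + b11 * z + u[:, 1]  # (m,)
    y = intercept[:, None] + slope[:, None] * x[None, :] + eps
    if config.clip_unit_interval:
        y = np.clip(y, 0.0, 1.0)
    return y.ravel()


def simulate_dataset(
    config: SimulationConfig, replicate_index: int = 0
) -> tuple[LongitudinalDataset, pd.DataFrame]:
    """Generate one full replicate: dataset plus truth table.

    The truth table records, per CpG, its scenario label ("null" for the
    non-causal CpGs) and the true (b00, b01, b10, b11).  Causal CpGs are
    placed at random positions among the ``n_cpgs`` CpGs, one per scenario.
    """
    rng = replicate_rng(config, replicate_index)
    individuals = simulate_individuals(config, rng)
    m, r = config.n_individuals, config.repeats

    causal_pos = rng.choice(config.n_cpgs, size=config.n_causal, replace=False)
    scenario_at = {int(p): sc for p, sc in zip(causal_pos, config.scenarios)}

    lo, hi = config.beta00_range
    beta00s = rng.uniform(lo, hi, size=config.n_cpgs)

    cpg_ids = [f"cpg{i:04d}" for i in range(config.n_cpgs)]
    beta = np.empty((config.n_cpgs, m * r))
    truth_rows = []
    for i in range(config.n_cpgs):
        sc = scenario_at.get(i)
        beta[i] = simulate_cpg(individuals, sc, config, rng, beta00=beta00s[i])
        truth_rows.append(
            {
                "cpg_id": cpg_ids[i],
                "scenario": sc.label if sc is not None else "null",
                "beta00": beta00s[i],
                "beta01": sc.beta01 if sc is not None else 0.0,
                "beta10": sc.beta10 if sc is not None else 0.0,
                "beta11": sc.beta11 if sc is not None else 0.0,
            }
        )

    ages = config.ages
    samples = pd.DataFrame(
        {
            "observation_id": [
                f"{ind}_t{k}"
                for ind in individuals["individual_id"]
                for k in range(r)
            ],
            "individual_id": np.repeat(individuals["individual_id"].to_numpy(), r),
            "age": np.tile(ages, m),
            "exposure": np.repeat(individuals["exposure"].to_numpy(), r),
        }
    )
    dataset = LongitudinalDataset(cpg_ids=cpg_ids, beta=beta, samples=samples)
    truth = pd.DataFrame(truth_rows)
    return dataset, truth
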