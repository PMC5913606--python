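"""Analysis configuration and config-file parsing."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .datamodel import ValidationError

VALID_STRATEGIES = (
    "baseline",
    "any_timepoint",
    "all_timepoints",
    "lmm_intercept",
    "lmm_intercept_slope",
    "robust_lm",
)

VALID_DF_METHODS = ("normal", "t_clusters_minus_p")


@dataclass(frozen=True)
class AnalysisConfig:
    """Settings shared by every fitting strategy.

    Attributes
    ----------
    significance_threshold
        Per-test p-value threshold for declaring a CpG a hit.  The default
        is the conventional epigenome-wide threshold 1e-7.
    age_origin
        Age (years) at which the intercept parameters are evaluated; age is
        centred at this value before model fitting so that the exposure main
        effect is a baseline effect.  ``None`` means the minimum age present
        in the data.
    covariates
        Names of sample-sheet columns entered as additional fixed effects.
    strategy
        Optional strategy selector for hit classification.
    small_sample_correction
        Multiply the sandwich "meat" by m/(m-1) (CR1).  Off by default: with
        hundreds of clusters the correction is negligible.
    df_method
        Reference distribution for Wald p-values: standard normal
        (``normal``) or Student t with m - p degrees of freedom
        (``t_clusters_minus_p``).
    timepoint_tolerance
        Half-width (years) of the age window used to assign observations to
        a nominal time-point in cross-sectional EWAS.
    """

    significance_threshold: float = 1e-7
    age_origin: float | None = None
    covariates: tuple[str, ...] = ()
    strategy: str | None = None
    small_sample_correction: bool = False
    df_method: str = "normal"
    timepoint_tolerance: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.significance_threshold < 1.0):
            raise ValidationError(
                f"significance_threshold must lie in (0, 1), got {self.significance_threshold}"
            )
        if self.strategy is not None and self.strategy not in VALID_STRATEGIES:
            raise ValidationError(
                f"unknown strategy {self.strategy!r}; valid: {VALID_STRATEGIES}"
            )
        if self.df_method not in VALID_DF_METHODS:
            raise ValidationError(
                f"unknown df_method {self.df_method!r}; valid: {VALID_DF_METHODS}"
            )
        if self.timepoint_tolerance < 0:
            raise ValidationError("timepoint_tolerance must be >= 0")
        object.__setattr__(self, "covariates", tuple(self.covariates))


@dataclass(frozen=True)
class RunConfig:
    """Bundle of the analysis and simulation sections of a config file."""

    analysis: AnalysisConfig
    simulation: "object"  # SimulationConfig; typed loosely to avoid cycles


def _build_dataclass(cls, mapping: dict, section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ValidationError(
            f"unknown key(s) in {section!r} config section: {sorted(unknown)}"
        )
    return cls(**mapping)


def load_config(path: str | Path) -> RunConfig:
    """Parse a YAML/JSON config document into analysis + simulation configs.

    The document may contain ``analysis:`` and ``simulation:`` sections;
    either may be omitted, in which case all defaults apply.  Unknown keys
    are rejected rather than ignored.
    """
    from .simulate import SimulationConfig  # local import: avoid cycle

    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValidationError(f"config file {path} must be a mapping at top level")
    unknown = set(raw) - {"analysis", "simulation"}
    if unknown:
        raise ValidationError(f"unknown top-level config section(s): {sorted(unknown)}")
    ana = raw.get("analysis") or {}
    sim = raw.get("simulation") or {}
    if "covariates" in ana and ana["covariates"] is not None:
        ana["covariates"] = tuple(ana["covariates"])
    analysis = _build_dataclass(AnalysisConfig, ana, "analysis")
    simulation = SimulationConfig.from_mapping(sim)
    return RunConfig(analysis=analysis, simulation=simulation)
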