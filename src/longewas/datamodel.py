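"""Core containers for longitudinal methylation data.

A longitudinal methylation study pairs a CpG-by-observation matrix of beta
values with a long-format sample sheet: one row per observation (an
individual measured at one age), clustered by individual.  The exposure is
an individual-level binary variable, so it must be constant across the
repeated measures of each individual.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REQUIRED_SAMPLE_COLUMNS = ("observation_id", "individual_id", "age", "exposure")

#: canonical column order of a result table
RESULT_COLUMNS = (
    "cpg_id",
    "strategy",
    "parameter",
    "estimate",
    "se",
    "statistic",
    "p_value",
    "n_obs",
    "n_clusters",
    "status",
)

#: parameters counted as "exposure-related" when classifying hits
EXPOSURE_PARAMETERS = ("exposure", "exposure:age")


class ValidationError(ValueError):
    """A dataset or configuration violates a structural invariant."""


class AlignmentError(ValidationError):
    """Beta-matrix columns and sample-sheet rows do not describe the same observations."""


@dataclass
class LongitudinalDataset:
    """Paired methylation matrix and long-format sample sheet.

    Parameters
    ----------
    cpg_ids
        CpG identifiers, one per row of ``beta``.
    beta
        Methylation values, CpGs x observations.  ``NaN`` marks a missing
        measurement; finite values are expected to lie in [0, 1] for real
        beta values but this is not enforced (model-generated trajectories
        may stray outside the unit interval).
    samples
        One row per observation with at least the columns
        ``observation_id``, ``individual_id``, ``age``, ``exposure``.
        Extra columns are available as covariates.
    """

    cpg_ids: list[str]
    beta: np.ndarray
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.samples = self.samples.reset_index(drop=True)
        self.validate()

    # -- structure ---------------------------------------------------------

    @property
    def n_cpgs(self) -> int:
        return self.beta.shape[0]

    @property
    def n_obs(self) -> int:
        return self.beta.shape[1]

    @property
    def n_individuals(self) -> int:
        return self.samples["individual_id"].nunique()

    @property
    def cluster_sizes(self) -> pd.Series:
        """Number of observations per individual (n_j)."""
        return self.samples.groupby("individual_id", sort=True).size()

    @property
    def ages(self) -> np.ndarray:
        return self.samples["age"].to_numpy(dtype=float)

    @property
    def exposure(self) -> np.ndarray:
        return self.samples["exposure"].to_numpy(dtype=float)

    @property
    def covariate_columns(self) -> list[str]:
        return [c for c in self.samples.columns if c not in REQUIRED_SAMPLE_COLUMNS]

    def validate(self) -> None:
        missing = [c for c in REQUIRED_SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing:
            raise ValidationError(f"sample sheet missing required column(s): {missing}")
        if self.beta.ndim != 2:
            raise ValidationError("beta must be a 2-D CpGs x observations matrix")
        if len(self.cpg_ids) != self.beta.shape[0]:
            raise ValidationError(
                f"{len(self.cpg_ids)} CpG ids but beta has {self.beta.shape[0]} rows"
            )
        if len(self.samples) != self.beta.shape[1]:
            raise AlignmentError(
                f"sample sheet has {len(self.samples)} observations but beta has "
                f"{self.beta.shape[1]} columns"
            )
        obs = self.samples["observation_id"]
        if obs.duplicated().any():
            dup = obs[obs.duplicated()].iloc[0]
            raise ValidationError(f"duplicate observation_id {dup!r}")
        ages = self.samples["age"]
        if not np.all(np.isfinite(ages.to_numpy(dtype=float))):
            bad = self.samples.loc[~np.isfinite(ages.to_numpy(dtype=float)), "observation_id"]
            raise ValidationError(f"non-finite age for observation(s) {list(bad)[:5]}")
        expo = self.samples["exposure"].to_numpy(dtype=float)
        if not np.all(np.isin(expo, (0.0, 1.0))):
            raise ValidationError("exposure must be binary 0/1")
        # exposure is an individual-level variable
        per_ind = self.samples.groupby("individual_id")["exposure"].nunique()
        varying = per_ind[per_ind > 1]
        if len(varying):
            raise ValidationError(
                f"exposure varies within individual(s) {list(varying.index)[:5]}; "
                "exposure must be constant within each individual"
            )
        if np.isinf(self.beta).any():
            r, c = np.argwhere(np.isinf(self.beta))[0]
            raise ValidationError(
                f"non-finite beta value at CpG {self.cpg_ids[r]!r}, "
                f"observation {self.samples['observation_id'].iloc[c]!r}"
            )

    def equals(self, other: "LongitudinalDataset") -> bool:
        """NaN-aware equality of ids, matrix and sample sheet."""
        if self.cpg_ids != other.cpg_ids:
            return False
        if self.beta.shape != other.beta.shape:
            return False
        if not np.array_equal(self.beta, other.beta, equal_nan=True):
            return False
        try:
            pd.testing.assert_frame_equal(self.samples, other.samples, check_like=False)
        except AssertionError:
            return False
        return True


@dataclass
class ResultTable:
    """Per-CpG inference results in long form.

    One row per (CpG, strategy, parameter) with estimate, standard error,
    test statistic and p-value; ``status`` records per-CpG fitting outcomes
    (``ok``, ``unfit``, ``boundary``, ``max_iter``, ``failed``,
    ``unreliable``).
    """

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if len(self.table):
            missing = [c for c in RESULT_COLUMNS if c not in self.table.columns]
            if missing:
                raise ValidationError(f"result table missing column(s): {missing}")
            self.table = self.table.loc[:, list(RESULT_COLUMNS)].reset_index(drop=True)
            pvals = self.table["p_value"].to_numpy(dtype=float)
            finite = np.isfinite(pvals)
            if np.any((pvals[finite] < 0) | (pvals[finite] > 1)):
                raise ValidationError("p-values must lie in [0, 1]")
            ses = self.table["se"].to_numpy(dtype=float)
            if np.any(ses[np.isfinite(ses)] < 0):
                raise ValidationError("standard errors must be non-negative")

    def __len__(self) -> int:
        return len(self.table)

    def exposure_pvalues(self, parameters: tuple[str, ...] = EXPOSURE_PARAMETERS) -> pd.Series:
        """Minimum p-value over the exposure-related parameters, per CpG."""
        sub = self.table[self.table["parameter"].isin(parameters)]
        return sub.groupby("cpg_id", sort=False)["p_value"].min()

    def hits(
        self,
        threshold: float,
        parameters: tuple[str, ...] = EXPOSURE_PARAMETERS,
    ) -> set[str]:
        """CpGs whose smallest exposure-related p-value falls below ``threshold``."""
        pmin = self.exposure_pvalues(parameters)
        return set(pmin.index[pmin < threshold])
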