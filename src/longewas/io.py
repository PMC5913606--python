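"""Delimited-text readers and writers.

Formats
-------
beta matrix
    TSV (comma autodetected), first column ``cpg_id``, one column per
    observation id, values decimal or ``NA`` for missing.
sample sheet
    TSV with required columns ``observation_id``, ``individual_id``,
    ``age``, ``exposure``; extra columns are covariates.
results
    Long-form TSV, one row per (CpG, strategy, parameter), full float
    precision so that a read-back reproduces every value bit-for-bit.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    RESULT_COLUMNS,
    REQUIRED_SAMPLE_COLUMNS,
    AlignmentError,
    LongitudinalDataset,
    ResultTable,
    ValidationError,
)


class ParseError(ValueError):
    """A file could not be parsed as the expected delimited-text format."""


def _read_table(path: Path) -> pd.DataFrame:
    """Read a delimited text file, TSV by default with comma autodetected."""
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if "\t" in first else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, na_values=[])


def read_dataset(beta_path: str | Path, samples_path: str | Path) -> LongitudinalDataset:
    """Read and align a beta matrix and sample sheet into a validated dataset.

    Beta columns are reordered to the sample-sheet observation order.
    Raises :class:`AlignmentError` when the two files do not describe the
    same set of observations and :class:`ParseError` on non-numeric values.
    """
    beta_path, samples_path = Path(beta_path), Path(samples_path)
    braw = _read_table(beta_path)
    if braw.columns[0] != "cpg_id":
        raise ParseError(
            f"{beta_path}: first column must be 'cpg_id', got {braw.columns[0]!r}"
        )
    samples = _read_table(samples_path)
    missing_cols = [c for c in REQUIRED_SAMPLE_COLUMNS if c not in samples.columns]
    if missing_cols:
        raise ValidationError(
            f"{samples_path}: missing required column(s) {missing_cols}"
        )

    obs_ids = samples["observation_id"].tolist()
    beta_obs = list(braw.columns[1:])
    missing_in_beta = sorted(set(obs_ids) - set(beta_obs))
    extra_in_beta = sorted(set(beta_obs) - set(obs_ids))
    if missing_in_beta or extra_in_beta:
        raise AlignmentError(
            f"observation ids disagree between {beta_path.name} and "
            f"{samples_path.name}: missing from beta {missing_in_beta[:5]}, "
            f"absent from sample sheet {extra_in_beta[:5]}"
        )

    values = braw[obs_ids]
    try:
        beta = values.replace("NA", np.nan).astype(float).to_numpy()
    except ValueError as exc:
        raise ParseError(f"{beta_path}: non-numeric beta value ({exc})") from exc

    for col in ("age", "exposure"):
        try:
            samples[col] = samples[col].astype(float)
        except ValueError as exc:
            raise ParseError(f"{samples_path}: non-numeric {col} ({exc})") from exc
    for col in samples.columns:
        if col in ("observation_id", "individual_id", "age", "exposure"):
            continue
        try:
            samples[col] = samples[col].replace("NA", np.nan).astype(float)
        except ValueError:
            pass  # string covariates stay as strings

    return LongitudinalDataset(
        cpg_ids=braw["cpg_id"].tolist(), beta=beta, samples=samples
    )


def write_dataset(
    dataset: LongitudinalDataset,
    beta_path: str | Path,
    samples_path: str | Path,
) -> None:
    """Write a dataset as a beta TSV and sample-sheet TSV (full precision)."""
    bdf = pd.DataFrame(dataset.beta, columns=dataset.samples["observation_id"])
    bdf.insert(0, "cpg_id", dataset.cpg_ids)
    bdf.to_csv(beta_path, sep="\t", index=False, na_rep="NA")
    dataset.samples.to_csv(samples_path, sep="\t", index=False, na_rep="NA")


def write_results(results: ResultTable, path: str | Path) -> None:
    """Write a result table as TSV with deterministic column order.

    Floats are written with ``repr`` precision so re-reading reproduces the
    values exactly.  An empty table is an error, never a silent empty file.
    """
    if len(results) == 0:
        raise ValidationError("refusing to write an empty result table")
    results.table.loc[:, list(RESULT_COLUMNS)].to_csv(
        path, sep="\t", index=False, na_rep="NA"
    )


def read_results(path: str | Path) -> ResultTable:
    """Read back a result table written by :func:`write_results`."""
    df = pd.read_csv(path, sep="\t", dtype={"cpg_id": str, "strategy": str,
                                            "parameter": str, "status": str})
    return ResultTable(df)


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"cpg_id": str, "scenario": str})
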