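"""Readers and writers for the pipeline's plain-text artifacts.

Expression data travel as long-format CSV with header
``experiment,gene,time_h,replicate,value``; fit tables, cost curves and sweep
results as TSV; model structures and model sets as JSON.  All numeric output
is written at full precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import DATA_COLUMNS, ExpressionDataset
from .terms import RegulatoryModel


class DataFormatError(ValueError):
    pass


def read_expression_csv(path) -> ExpressionDataset:
    """Read and validate a long-format expression CSV.

    Rejects malformed headers, non-numeric or negative values, missing cells
    and duplicate (gene, time, replicate) records, naming the offending row
    (1-based, excluding the header) in the error message.
    """
    path = Path(path)
    table = pd.read_csv(path, dtype={"experiment": str, "gene": str})
    if tuple(table.columns) != DATA_COLUMNS:
        raise DataFormatError(
            f"{path}: malformed header {tuple(table.columns)}; expected {DATA_COLUMNS}"
        )
    for column in ("time_h", "value"):
        numeric = pd.to_numeric(table[column], errors="coerce")
        bad = np.flatnonzero(numeric.isna().to_numpy())
        if bad.size:
            raise DataFormatError(f"{path}: non-numeric {column} in row {bad[0] + 1}")
        table[column] = numeric
    missing = np.flatnonzero(table.isna().any(axis=1).to_numpy())
    if missing.size:
        raise DataFormatError(f"{path}: missing cell in row {missing[0] + 1}")
    negative = np.flatnonzero((table["value"] < 0).to_numpy())
    if negative.size:
        raise DataFormatError(f"{path}: negative value in row {negative[0] + 1}")
    replicate = pd.to_numeric(table["replicate"], errors="coerce")
    bad = np.flatnonzero(replicate.isna().to_numpy())
    if bad.size:
        raise DataFormatError(f"{path}: non-numeric replicate in row {bad[0] + 1}")
    table["replicate"] = replicate.astype(int)
    duplicated = table.duplicated(subset=["experiment", "gene", "time_h", "replicate"])
    dup = np.flatnonzero(duplicated.to_numpy())
    if dup.size:
        raise DataFormatError(f"{path}: duplicate (gene, time, replicate) in row {dup[0] + 1}")
    experiments = table["experiment"].unique()
    experiment = experiments[0] if len(experiments) == 1 else "mixed"
    return ExpressionDataset(experiment=experiment, table=table)


def write_expression_csv(dataset: ExpressionDataset, path) -> None:
    dataset.table.to_csv(path, index=False)


def write_model_json(model: RegulatoryModel, path) -> None:
    Path(path).write_text(model.to_json() + "\n")


def read_model_json(path) -> RegulatoryModel:
    return RegulatoryModel.from_json(Path(path).read_text())


def write_table_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_table_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(doc, path) -> None:
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
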