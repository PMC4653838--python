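"""Readers, writers and patient alignment for delimited-text matrices.

Canonical on-disk layout: TSV with patients as rows, the first column
holding patient ids and the header row holding feature (or patient) ids.
Square similarity matrices use the same id order on rows and columns.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_labels",
    "write_labels",
    "read_clinical",
    "align_patients",
]

logger = logging.getLogger("ibfe")


def read_matrix(path, sep: str = "\t", transpose: bool = False) -> pd.DataFrame:
    """Read a patients x features numeric matrix from delimited text.

    The first column must hold patient ids and the first row a header.
    ``transpose=True`` accommodates features-as-rows exports.  Duplicate
    ids and non-numeric or non-finite cells are rejected with an error
    naming the offender.
    """
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.columns.size == 0:
        raise ValueError(f"{path}: no feature columns (missing header?)")
    if transpose:
        df = df.T
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate patient id(s) {dupes}")
    df.index = df.index.astype(str)
    df.index.name = "patient_id"
    df.columns.name = None
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as err:
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise ValueError(
                f"{path}: non-numeric value in column {col!r}, row {row!r}"
            ) from err
    values = df.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(
            f"{path}: non-finite value at row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    return df


def write_matrix(df: pd.DataFrame, path, sep: str = "\t") -> None:
    """Write a matrix in the canonical layout (ids in the first column)."""
    df.to_csv(path, sep=sep, index_label="patient_id")


def read_labels(path, sep: str = "\t") -> pd.Series:
    """Read a cluster-label table (columns ``patient_id``, ``cluster``)."""
    df = pd.read_csv(path, sep=sep)
    if not {"patient_id", "cluster"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns 'patient_id' and 'cluster'")
    if df["patient_id"].duplicated().any():
        dupes = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        raise ValueError(f"{path}: duplicate patient id(s) {dupes}")
    return df.set_index("patient_id")["cluster"]


def write_labels(labels: pd.Series, path, sep: str = "\t") -> None:
    frame = labels.rename("cluster").rename_axis("patient_id").reset_index()
    frame.to_csv(path, sep=sep, index=False)


def read_clinical(path, sep: str = "\t") -> pd.DataFrame:
    """Read a clinical table (``patient_id``, ``time``, ``event``)."""
    df = pd.read_csv(path, sep=sep)
    missing = {"patient_id", "time", "event"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    df["patient_id"] = df["patient_id"].astype(str)
    return df


def align_patients(datasets: Sequence[pd.DataFrame]) -> list[pd.DataFrame]:
    """Restrict all data types to their shared patients, in sorted order.

    Patients absent from any data type are dropped (counts are logged per
    data type); an empty intersection is an error.  The canonical sorted
    order makes downstream results independent of input row order.
    """
    if len(datasets) == 0:
        raise ValueError("need at least one dataset")
    common = datasets[0].index
    for df in datasets[1:]:
        common = common.intersection(df.index)
    if len(common) == 0:
        raise ValueError("no patient is shared by all datasets")
    common = common.sort_values()
    aligned = []
    for i, df in enumerate(datasets):
        dropped = len(df.index) - len(common)
        if dropped:
            logger.info("dataset %d: dropped %d patient(s) during alignment", i + 1, dropped)
        aligned.append(df.loc[common])
    return aligned
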