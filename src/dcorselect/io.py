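"""Loading, cleaning and binarization of tabular data (CSV and ARFF).

The expected layout is the classic UCI arrhythmia shape: rows are samples,
the last column is the class label (1 = normal rhythm, 2–16 = arrhythmia
subtypes), and ``?`` marks a missing value.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.io import arff as scipy_arff

from ._validation import ValidationError

__all__ = ["RawTable", "CleaningReport", "load_table", "clean_features",
           "binarize_target", "write_arff"]


@dataclass
class RawTable:
    features: pd.DataFrame       # numeric with NaN for missing
    target: pd.Series
    class_column: str

    @property
    def n_samples(self) -> int:
        return len(self.features)

    @property
    def n_features(self) -> int:
        return self.features.shape[1]


@dataclass
class CleaningReport:
    dropped_missing: list[str] = field(default_factory=list)
    dropped_constant: list[str] = field(default_factory=list)
    dropped_rows: int = 0

    def summary(self) -> str:
        return (f"dropped {len(self.dropped_missing)} columns with missing values, "
                f"{len(self.dropped_constant)} zero-variance columns, "
                f"{self.dropped_rows} rows")


def load_table(path, format: str | None = None, missing_token: str = "?",
               class_column: str | int = -1) -> RawTable:
    """Read a CSV or ARFF table; missing tokens become NaN.

    ``class_column`` may be a name or positional index (default: last).
    """
    fmt = format
    if fmt is None:
        fmt = "arff" if str(path).lower().endswith(".arff") else "csv"
    if fmt == "csv":
        df = pd.read_csv(path, na_values=[missing_token], skipinitialspace=True)
    elif fmt == "arff":
        data, meta = scipy_arff.loadarff(path)
        df = pd.DataFrame(data)
        for c in df.columns:  # decode nominal byte strings
            if df[c].dtype == object:
                df[c] = df[c].str.decode("utf-8")
                df[c] = df[c].replace(missing_token, np.nan)
    else:
        raise ValidationError(f"unknown format {fmt!r}")
    if df.empty:
        raise ValidationError("table is empty")

    col = df.columns[class_column] if isinstance(class_column, int) else class_column
    if col not in df.columns:
        raise ValidationError(f"class column {col!r} not found")
    target = pd.to_numeric(df[col], errors="raise")
    feats = df.drop(columns=[col])
    # nominal columns consumed as numeric codes
    for c in feats.columns:
        if feats[c].dtype == object:
            feats[c] = pd.to_numeric(feats[c], errors="coerce").fillna(
                pd.Series(pd.Categorical(feats[c]).codes, index=feats.index).replace(-1, np.nan)
            )
        else:
            feats[c] = pd.to_numeric(feats[c], errors="raise")
    return RawTable(features=feats.astype(float), target=target, class_column=col)


def clean_features(raw: RawTable, drop_rows: bool = False) -> tuple[pd.DataFrame, np.ndarray, CleaningReport]:
    """Drop missing-value columns (or rows), then zero-variance columns.

    Residual non-finite cells are zeroed.  Returns the cleaned feature
    table, the (possibly row-filtered) target, and a report of what was
    dropped and why.
    """
    report = CleaningReport()
    feats = raw.features.copy()
    target = raw.target.to_numpy()
    if drop_rows:
        keep = ~feats.isna().any(axis=1)
        report.dropped_rows = int((~keep).sum())
        feats = feats.loc[keep]
        target = target[keep.to_numpy()]
    else:
        missing_cols = feats.columns[feats.isna().any()].tolist()
        report.dropped_missing = missing_cols
        feats = feats.drop(columns=missing_cols)
    arr = feats.to_numpy(dtype=float)
    arr = np.where(np.isfinite(arr), arr, 0.0)
    feats = pd.DataFrame(arr, columns=feats.columns, index=feats.index)
    constant = feats.columns[feats.nunique() <= 1].tolist()
    report.dropped_constant = constant
    feats = feats.drop(columns=constant)
    if feats.shape[1] == 0:
        raise ValidationError("all feature columns were dropped during cleaning")
    return feats, target, report


def binarize_target(labels) -> np.ndarray:
    """Class 1 (normal) → 0; classes 2–16 (any arrhythmia) → 1."""
    lab = np.asarray(labels)
    lab = lab.astype(float)
    if not np.all(np.isfinite(lab)):
        raise ValidationError("non-finite class labels")
    lab = lab.astype(int)
    if lab.min() < 1 or lab.max() > 16:
        raise ValidationError(f"class labels outside 1..16: [{lab.min()}, {lab.max()}]")
    return (lab != 1).astype(int)


def write_arff(df: pd.DataFrame, path, relation: str = "table") -> None:
    """Minimal numeric ARFF writer (NaN serialized as '?')."""
    with open(path, "w") as fh:
        fh.write(f"@RELATION {relation}\n\n")
        for c in df.columns:
            fh.write(f"@ATTRIBUTE {c} NUMERIC\n")
        fh.write("\n@DATA\n")
        for _, row in df.iterrows():
            cells = ["?" if not np.isfinite(v) else f"{v:.12g}" for v in row]
            fh.write(",".join(cells) + "\n")
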