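"""Delimited-text readers and writers.

The on-disk convention mirrors the common neuroimaging-harmonization input
triplet: a features-by-subjects matrix (first column feature IDs, header row
subject IDs), a subjects-by-covariates table, and batch labels given either
as a named column of the covariate table or as a single-column file.
Comma and tab delimiters are autodetected; a transpose flag accepts the
subjects-by-features dialect.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import CovariateDesign, FeatureMatrix

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_table",
    "design_from_dataframe",
    "read_batch_labels",
    "write_harmonized",
]


def _detect_sep(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def _require_numeric(df: pd.DataFrame, path) -> pd.DataFrame:
    coerced = df.apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna() & ~df.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric cell at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    if coerced.isna().to_numpy().any():
        r, c = np.argwhere(coerced.isna().to_numpy())[0]
        raise ValueError(
            f"{path}: missing value at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    return coerced


def read_matrix(path, transpose: bool = False) -> FeatureMatrix:
    """Read a features-by-subjects matrix from delimited text.

    ``transpose=True`` reads a subjects-by-features file into the same
    canonical orientation.
    """
    path = Path(path)
    sep = _detect_sep(path)
    with open(path) as fh:  # check the raw header: pandas silently mangles duplicates
        header = fh.readline().rstrip("\n").split(sep)[1:]
    dups = sorted({c for c in header if header.count(c) > 1})
    if dups:
        raise ValueError(f"{path}: duplicate column IDs {dups}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate row IDs {dups}")
    df = _require_numeric(df, path)
    if transpose:
        df = df.T
    return FeatureMatrix(
        values=df.to_numpy(dtype=float),
        feature_ids=[str(x) for x in df.index],
        subject_ids=[str(x) for x in df.columns],
    )


def write_matrix(matrix: FeatureMatrix, path, digits: int = 10) -> None:
    """Write a FeatureMatrix; delimiter follows the suffix (.tsv -> tab)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    df = pd.DataFrame(matrix.values, index=matrix.feature_ids, columns=matrix.subject_ids)
    df.index.name = "feature"
    df.to_csv(path, sep=sep, float_format=f"%.{digits}g")


def read_table(path) -> pd.DataFrame:
    """Read a subjects-by-covariates table (first column subject IDs)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path), index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate subject IDs {dups}")
    return df


def design_from_dataframe(df: pd.DataFrame, subject_ids=None) -> CovariateDesign:
    """Build a CovariateDesign, one-hot encoding non-numeric columns.

    When ``subject_ids`` is given the rows are aligned to that order and
    missing subjects are reported.
    """
    if subject_ids is not None:
        missing = [s for s in subject_ids if s not in df.index.astype(str)]
        if missing:
            raise ValueError(f"covariate table is missing subjects: {missing[:5]}")
        df = df.loc[[str(s) for s in subject_ids]] if df.index.dtype == object else df.loc[subject_ids]
    encoded = pd.get_dummies(df, drop_first=True, dtype=float)
    return CovariateDesign(encoded.to_numpy(dtype=float), [str(c) for c in encoded.columns])


def read_batch_labels(batch, covariates: pd.DataFrame = None, n_subjects: int = None) -> np.ndarray:
    """Resolve batch labels from a covariate column name or a one-label-per-line file."""
    if covariates is not None and str(batch) in covariates.columns:
        return covariates[str(batch)].to_numpy()
    path = Path(str(batch))
    if path.exists():
        labels = [line.strip() for line in path.read_text().splitlines() if line.strip()]
        if n_subjects is not None and len(labels) == n_subjects + 1:
            labels = labels[1:]  # tolerate a header line
        return np.asarray(labels)
    raise ValueError(
        f"batch {batch!r} is neither a column of the covariate table nor an existing file"
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating, np.bool_)):
        return obj.item()
    return obj


def write_harmonized(dataset, path, feature_ids=None, subject_ids=None,
                     with_components: bool = False, digits: int = 10) -> None:
    """Write a HarmonizedDataset in the input layout.

    With ``with_components`` a sidecar directory ``<path>.components/``
    receives one matrix file per additive component plus a
    ``provenance.json`` recording method, options, and fitted scales.
    """
    fm = FeatureMatrix(dataset.values, feature_ids, subject_ids)
    write_matrix(fm, path, digits=digits)
    if not with_components:
        return
    outdir = Path(str(path) + ".components")
    outdir.mkdir(parents=True, exist_ok=True)
    for name, comp in dataset.components.items():
        write_matrix(FeatureMatrix(comp, fm.feature_ids, fm.subject_ids),
                     outdir / f"{name}.tsv", digits=digits)
    record = {"method": dataset.method, "provenance": _jsonable(dataset.provenance)}
    (outdir / "provenance.json").write_text(json.dumps(record, indent=2))
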