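"""Core containers for multi-scanner feature data.

The package works on a features-by-subjects matrix ``Y`` (V features, n
subjects), a subjects-by-covariates design ``X`` (n x q), and a per-subject
scanner (batch) label vector that partitions the columns of ``Y`` into
per-scanner blocks ``Y = [Y_1; ...; Y_M]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FeatureMatrix", "ScannerPartition", "CovariateDesign"]


def _check_matrix(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 2-dimensional, got shape {arr.shape}")
    if not np.isfinite(arr).all():
        bad = np.argwhere(~np.isfinite(arr))[0]
        raise ValueError(
            f"{name} contains missing or non-finite entries "
            f"(first at row {bad[0]}, column {bad[1]}); complete data are required"
        )
    return arr


def _check_unique(ids, name: str) -> list:
    ids = [str(x) for x in ids]
    seen, dups = set(), []
    for x in ids:
        if x in seen:
            dups.append(x)
        seen.add(x)
    if dups:
        raise ValueError(f"duplicate {name}: {sorted(set(dups))}")
    return ids


@dataclass
class FeatureMatrix:
    """A V x n matrix of V features measured on n subjects.

    Parameters
    ----------
    values : ndarray of shape (V, n)
        Feature values, features in rows and subjects in columns. Missing
        entries are rejected.
    feature_ids, subject_ids : sequence of str, optional
        Unique row / column labels; generated when omitted.
    """

    values: np.ndarray
    feature_ids: list = None
    subject_ids: list = None

    def __post_init__(self):
        self.values = _check_matrix(self.values, "feature matrix")
        V, n = self.values.shape
        if V < 2 or n < 2:
            raise ValueError(f"need at least 2 features and 2 subjects, got V={V}, n={n}")
        if self.feature_ids is None:
            self.feature_ids = [f"feature{k + 1}" for k in range(V)]
        if self.subject_ids is None:
            self.subject_ids = [f"subject{k + 1}" for k in range(n)]
        self.feature_ids = _check_unique(self.feature_ids, "feature_ids")
        self.subject_ids = _check_unique(self.subject_ids, "subject_ids")
        if len(self.feature_ids) != V:
            raise ValueError(f"{len(self.feature_ids)} feature_ids for {V} rows")
        if len(self.subject_ids) != n:
            raise ValueError(f"{len(self.subject_ids)} subject_ids for {n} columns")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.values.shape[1]


@dataclass
class ScannerPartition:
    """Subject-to-scanner assignment inducing column blocks of ``Y``.

    Scanner identifiers are held in sorted order; ``sizes[i]`` is the number
    of subjects on scanner ``scanner_ids[i]``. Every scanner must contribute
    at least 2 subjects (per-scanner SVDs and covariances need them).
    """

    labels: np.ndarray

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if labels.ndim != 1 or labels.size < 2:
            raise ValueError("scanner labels must be a 1-d sequence of length n >= 2")
        self.labels = labels
        self.scanner_ids, inverse = np.unique(labels, return_inverse=True)
        self.sizes = np.bincount(inverse)
        self._inverse = inverse
        self._indices = [np.flatnonzero(inverse == i) for i in range(len(self.scanner_ids))]
        small = [str(s) for s, c in zip(self.scanner_ids, self.sizes) if c < 2]
        if small:
            raise ValueError(f"every scanner needs at least 2 subjects; too few on: {small}")

    @property
    def n_subjects(self) -> int:
        return self.labels.size

    @property
    def n_scanners(self) -> int:
        return len(self.scanner_ids)

    def indices(self, i: int) -> np.ndarray:
        """Column indices of scanner ``i`` (positional, sorted-label order)."""
        return self._indices[i]

    @property
    def scanner_index(self) -> np.ndarray:
        """Length-n vector mapping each subject to its scanner's position."""
        return self._inverse

    def blocks(self, matrix: np.ndarray) -> list:
        """Split a V x n matrix into per-scanner column blocks."""
        matrix = np.asarray(matrix)
        if matrix.shape[-1] != self.n_subjects:
            raise ValueError(
                f"matrix has {matrix.shape[-1]} columns but partition covers "
                f"{self.n_subjects} subjects"
            )
        return [matrix[..., idx] for idx in self._indices]


@dataclass
class CovariateDesign:
    """An n x q covariate table aligned to the subjects of a FeatureMatrix.

    ``q = 0`` (intercept-only modelling) is allowed. The design must have full
    column rank once an intercept column is prepended; exactly collinear
    columns are reported by name.
    """

    values: np.ndarray
    covariate_names: list = None

    def __post_init__(self):
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        if arr.ndim != 2:
            raise ValueError("covariate design must be 2-dimensional")
        if not np.isfinite(arr).all():
            raise ValueError("covariate design contains missing or non-finite entries")
        self.values = arr
        n, q = arr.shape
        if self.covariate_names is None:
            self.covariate_names = [f"x{k + 1}" for k in range(q)]
        self.covariate_names = _check_unique(self.covariate_names, "covariate names")
        if len(self.covariate_names) != q:
            raise ValueError(f"{len(self.covariate_names)} names for {q} covariates")
        if q:
            self._check_rank()

    @classmethod
    def empty(cls, n_subjects: int) -> "CovariateDesign":
        """Intercept-only design (q = 0)."""
        return cls(np.empty((n_subjects, 0)), [])

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.values.shape[1]

    def with_intercept(self) -> np.ndarray:
        """The n x (q+1) design matrix [1, X]."""
        n = self.n_subjects
        return np.column_stack([np.ones(n), self.values])

    def add_column(self, values, name: str) -> "CovariateDesign":
        values = np.asarray(values, dtype=float).reshape(-1)
        return CovariateDesign(
            np.column_stack([self.values, values]) if self.n_covariates else values[:, None],
            list(self.covariate_names) + [name],
        )

    def _check_rank(self):
        D = self.with_intercept()
        if np.linalg.matrix_rank(D) == D.shape[1]:
            return
        # walk columns, naming each one that lies in the span of its predecessors
        collinear = []
        kept = D[:, :1]
        for j, name in enumerate(self.covariate_names):
            col = D[:, j + 1]
            coef, *_ = np.linalg.lstsq(kept, col, rcond=None)
            if np.linalg.norm(col - kept @ coef) < 1e-8 * max(1.0, np.linalg.norm(col)):
                collinear.append(name)
            else:
                kept = np.column_stack([kept, col])
        raise ValueError(
            "covariate design is rank deficient after adding an intercept; "
            f"collinear columns: {collinear}"
        )
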