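"""Shared sklearn-style estimator plumbing for the harmonizers.

All harmonizers are transformers that take ``X`` of shape
``(n_subjects, n_features)`` (the sklearn orientation; internally the
methods work on the transposed V x n matrix), a required ``batch`` label
vector, and an optional covariate table. Harmonization is a joint model of
all subjects, so ``transform`` is only defined for the data the estimator
was fitted on; ``fit_transform`` is the intended entry point.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .datatypes import CovariateDesign, ScannerPartition

__all__ = ["BaseHarmonizer", "as_design"]


def as_design(covariates, n_subjects: int) -> CovariateDesign:
    """Coerce None / ndarray / DataFrame / CovariateDesign to a CovariateDesign."""
    if covariates is None:
        return CovariateDesign.empty(n_subjects)
    if isinstance(covariates, CovariateDesign):
        design = covariates
    elif isinstance(covariates, pd.DataFrame):
        from .io import design_from_dataframe

        design = design_from_dataframe(covariates)
    else:
        design = CovariateDesign(np.asarray(covariates, dtype=float))
    if design.n_subjects != n_subjects:
        raise ValueError(
            f"covariates describe {design.n_subjects} subjects but data has {n_subjects}"
        )
    return design


class BaseHarmonizer(TransformerMixin, BaseEstimator):
    """Base class: input validation, orientation, fitted-state handling."""

    def fit(self, X, y=None, *, batch=None, covariates=None):
        """Fit the harmonization model and compute the harmonized data.

        Parameters
        ----------
        X : array-like of shape (n_subjects, n_features)
        batch : array-like of shape (n_subjects,)
            Scanner/batch label per subject. Required.
        covariates : array-like, DataFrame or CovariateDesign, optional
            Subjects-by-covariates design whose effects are modelled and
            preserved. Covariates of interest for downstream testing should
            normally be left out (see the RELIEF docstring).
        """
        if batch is None:
            raise ValueError("batch labels are required: fit(X, batch=...)")
        X = check_array(X, dtype=float, ensure_min_samples=2, ensure_min_features=2)
        partition = batch if isinstance(batch, ScannerPartition) else ScannerPartition(np.asarray(batch))
        if partition.n_subjects != X.shape[0]:
            raise ValueError(
                f"{partition.n_subjects} batch labels for {X.shape[0]} subjects"
            )
        design = as_design(covariates, X.shape[0])
        dataset = self._harmonize(X.T.copy(), design, partition)
        self.dataset_ = dataset
        self.harmonized_ = dataset.values.T
        self.partition_ = partition
        self.design_ = design
        self.n_features_in_ = X.shape[1]
        self._fit_X = X
        return self

    def _harmonize(self, values, design, partition):  # pragma: no cover - abstract
        raise NotImplementedError

    def transform(self, X):
        """Return the harmonized data for the matrix the model was fitted on.

        Harmonization is estimated jointly from all subjects; there is no
        out-of-sample transform, so ``X`` must be the fitted data.
        """
        check_is_fitted(self, "harmonized_")
        X = check_array(X, dtype=float)
        if X.shape != self._fit_X.shape or not np.allclose(X, self._fit_X, equal_nan=False):
            raise ValueError(
                "transform is only defined for the data the harmonizer was fitted on; "
                "refit (or use fit_transform) to harmonize new data"
            )
        return self.harmonized_.copy()

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X, y, **fit_params).harmonized_.copy()

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.target_tags.required = False
        return tags
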