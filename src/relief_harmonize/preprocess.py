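"""Two-step regression preprocessing.

Step one fits, for every feature, an ordinary-least-squares model on an
intercept plus the observed covariates. Step two removes scanner-specific
means from the first-stage residuals, absorbing additive (location) scanner
effects. Optionally each residual row is rescaled to unit standard deviation
so that downstream noise estimation and factorization treat features on a
common scale; the scales are stored for exact inversion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import CovariateDesign, FeatureMatrix, ScannerPartition

__all__ = [
    "TwoStepRegressionFit",
    "fit_covariate_model",
    "remove_scanner_means",
    "scale_features",
    "two_step_regression",
]


@dataclass
class TwoStepRegressionFit:
    """Fitted pieces of the two-step regression.

    Attributes
    ----------
    intercepts : (V,) per-feature intercepts.
    coefficients : (V, q) per-feature covariate coefficients.
    scanner_means : (V, M) within-scanner means of first-stage residuals.
    residuals : (V, n) second-stage residuals (divided by ``feature_scales``
        when feature scaling is enabled).
    feature_scales : (V,) per-feature residual standard deviations used for
        scaling; all ones when scaling is disabled.
    """

    intercepts: np.ndarray
    coefficients: np.ndarray
    scanner_means: np.ndarray
    residuals: np.ndarray
    feature_scales: np.ndarray
    design: CovariateDesign
    partition: ScannerPartition

    def fitted_mean(self) -> np.ndarray:
        """V x n matrix of intercepts plus covariate effects."""
        out = np.broadcast_to(
            self.intercepts[:, None], (len(self.intercepts), self.design.n_subjects)
        ).copy()
        if self.design.n_covariates:
            out += self.coefficients @ self.design.values.T
        return out

    def scanner_mean_matrix(self) -> np.ndarray:
        """Expand the V x M scanner means to a V x n matrix."""
        return self.scanner_means[:, self.partition.scanner_index]

    def reconstruct(self) -> np.ndarray:
        """Rebuild the original data (exact, including feature scales)."""
        return (
            self.fitted_mean()
            + self.scanner_mean_matrix()
            + self.residuals * self.feature_scales[:, None]
        )


def _values(data) -> np.ndarray:
    return data.values if isinstance(data, FeatureMatrix) else np.asarray(data, dtype=float)


def fit_covariate_model(data, design: CovariateDesign):
    """Per-feature OLS of the data on an intercept plus covariates.

    Returns ``(intercepts, coefficients, residuals)`` with residuals
    orthogonal to the design columns. An intercept is always included, so
    with ``q = 0`` this reduces to row-centering.
    """
    Y = _values(data)
    if design.n_subjects != Y.shape[1]:
        raise ValueError(
            f"design has {design.n_subjects} subjects but data has {Y.shape[1]} columns"
        )
    D = design.with_intercept()
    coef, *_ = np.linalg.lstsq(D, Y.T, rcond=None)  # (q+1) x V
    residuals = Y - (D @ coef).T
    return coef[0], coef[1:].T, residuals


def remove_scanner_means(first_stage_residuals, partition: ScannerPartition):
    """Subtract within-scanner means per feature from first-stage residuals."""
    R = _values(first_stage_residuals)
    if R.shape[1] != partition.n_subjects:
        raise ValueError("residual columns and partition labels are misaligned")
    means = np.empty((R.shape[0], partition.n_scanners))
    for i in range(partition.n_scanners):
        means[:, i] = R[:, partition.indices(i)].mean(axis=1)
    second = R - means[:, partition.scanner_index]
    return means, second


def scale_features(second_stage_residuals, enabled: bool = True):
    """Divide each residual row by its (population) standard deviation.

    Returns ``(scaled_residuals, feature_scales)``; with ``enabled=False``
    the residuals pass through and the scales are all 1. Constant features
    are rejected because their scale is undefined.
    """
    R = _values(second_stage_residuals)
    if not enabled:
        return R.copy(), np.ones(R.shape[0])
    sd = R.std(axis=1)  # divisor n; inverted exactly afterwards
    floor = 1e-12 * max(1.0, float(np.abs(R).max(initial=0.0)))
    constant = np.flatnonzero(sd <= floor)
    if constant.size:
        raise ValueError(
            f"cannot scale features with zero residual variance: rows {constant.tolist()}"
        )
    return R / sd[:, None], sd


def two_step_regression(
    data,
    design: CovariateDesign,
    partition: ScannerPartition,
    scale: bool = False,
) -> TwoStepRegressionFit:
    """Run both regression steps (and optional feature scaling) in order."""
    Y = _values(data)
    if partition.n_subjects != Y.shape[1]:
        raise ValueError("partition labels and data columns are misaligned")
    intercepts, coefficients, first = fit_covariate_model(Y, design)
    scanner_means, second = remove_scanner_means(first, partition)
    residuals, scales = scale_features(second, enabled=scale)
    return TwoStepRegressionFit(
        intercepts=intercepts,
        coefficients=coefficients,
        scanner_means=scanner_means,
        residuals=residuals,
        feature_scales=scales,
        design=design,
        partition=partition,
    )
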