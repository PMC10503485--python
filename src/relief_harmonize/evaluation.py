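"""Harmonization-quality metrics.

Three complementary probes of residual scanner structure: the Frobenius norm
of the difference between scanner-specific covariance matrices (covariance
homogeneity), leave-one-out QDA prediction of the scanner label (a
mean-and-covariance-only classifier, so its accuracy reflects exactly the
structure harmonization should have removed; chance level means success),
and two-dimensional PCA projections for visual checks. All metrics regress
out covariate effects first so method comparisons are settings-matched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
from sklearn.metrics import auc, roc_curve

from .base import as_design
from .datatypes import FeatureMatrix, ScannerPartition
from .preprocess import fit_covariate_model

__all__ = [
    "EvaluationReport",
    "covariance_frobenius_diff",
    "qda_scanner_prediction",
    "pca_scores",
    "evaluate_harmonizations",
]


@dataclass
class EvaluationReport:
    """Per-method harmonization-quality metrics."""

    cov_frobenius_diff: dict
    qda_accuracy: dict
    qda_auc: dict
    pc_scores: dict
    settings: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        methods = sorted(self.cov_frobenius_diff)
        return pd.DataFrame(
            {
                "cov_frobenius_diff": [self.cov_frobenius_diff[m] for m in methods],
                "qda_accuracy": [self.qda_accuracy[m] for m in methods],
                "qda_auc": [self.qda_auc[m] for m in methods],
            },
            index=pd.Index(methods, name="method"),
        )


def _values(data):
    return data.values if isinstance(data, FeatureMatrix) else np.asarray(data, dtype=float)


def _as_partition(partition):
    return partition if isinstance(partition, ScannerPartition) else ScannerPartition(np.asarray(partition))


def _residualize(values, design):
    if design is None or design.n_covariates == 0:
        # center only; scanner prediction should not exploit the grand mean
        return values - values.mean(axis=1, keepdims=True)
    _, _, resid = fit_covariate_model(values, design)
    return resid


def covariance_frobenius_diff(data, partition, design=None, adjust_covariates: bool = True) -> float:
    """Frobenius norm of the difference between scanner covariance matrices.

    For two scanners this is ``||Cov_1 - Cov_2||_F`` of the per-scanner
    sample covariances (computed on covariate-adjusted residuals when
    ``adjust_covariates``). With more than two scanners the mean over all
    pairs is returned.
    """
    Y = _values(data)
    partition = _as_partition(partition)
    if partition.sizes.min() < 2:
        raise ValueError("every scanner needs at least 2 subjects for a covariance")
    if adjust_covariates:
        Y = _residualize(Y, as_design(design, Y.shape[1]) if design is not None else None)
    covs = [np.cov(blk, ddof=1) for blk in partition.blocks(Y)]
    M = len(covs)
    if M < 2:
        raise ValueError("covariance comparison needs at least 2 scanners")
    norms = [
        float(np.linalg.norm(covs[i] - covs[j]))
        for i in range(M)
        for j in range(i + 1, M)
    ]
    return float(np.mean(norms))


def qda_scanner_prediction(data, partition, design=None, shrinkage: float = 0.0):
    """Leave-one-out QDA prediction of the scanner label (two scanners).

    Covariate effects are regressed out first. Each subject is scored by a
    QDA model fitted on all other subjects; returns ``(accuracy, auc,
    roc_points)`` with accuracy at the posterior-0.5 rule and the positive
    class taken as the second scanner label in sorted order.

    ``shrinkage`` (sklearn's ``reg_param``, a convex pull of each class
    covariance toward a scaled identity) is required when any within-scanner
    sample size does not exceed the feature count.
    """
    Y = _values(data)
    partition = _as_partition(partition)
    if partition.n_scanners != 2:
        raise ValueError("scanner prediction is defined for exactly 2 scanners")
    Y = _residualize(Y, as_design(design, Y.shape[1]) if design is not None else None)
    V, n = Y.shape
    if shrinkage == 0.0 and partition.sizes.min() - 1 <= V:
        raise ValueError(
            "within-scanner sample size does not exceed the feature count, so the "
            "class covariances are singular; pass shrinkage > 0"
        )
    X = Y.T  # subjects x features
    y = partition.scanner_index
    positive = 1  # second scanner label in sorted order
    proba = np.empty(n)
    idx_all = np.arange(n)
    qda_kwargs = (
        {"solver": "eigen", "shrinkage": shrinkage} if shrinkage > 0 else {}
    )
    for j in range(n):
        train = idx_all != j
        model = QuadraticDiscriminantAnalysis(**qda_kwargs)
        model.fit(X[train], y[train])
        proba[j] = model.predict_proba(X[j : j + 1])[0, list(model.classes_).index(positive)]
    accuracy = float(np.mean((proba > 0.5) == (y == positive)))
    fpr, tpr, _ = roc_curve(y == positive, proba)
    return accuracy, float(auc(fpr, tpr)), np.column_stack([fpr, tpr])


def pca_scores(data, n_components: int = 2) -> np.ndarray:
    """Subject scores on the leading principal components.

    Features are centered across subjects; scores are the SVD projections
    (n_subjects x n_components). Sign convention: each component's
    largest-magnitude feature loading is made positive, so the output is
    deterministic.
    """
    Y = _values(data)
    centered = Y - Y.mean(axis=1, keepdims=True)
    U, s, Vt = np.linalg.svd(centered, full_matrices=False)
    k = min(n_components, len(s))
    signs = np.sign(U[np.abs(U[:, :k]).argmax(axis=0), np.arange(k)])
    signs[signs == 0] = 1.0
    scores = (s[:k] * signs * Vt[:k].T)[:, :k]
    if k < n_components:
        scores = np.column_stack([scores, np.zeros((Y.shape[1], n_components - k))])
    return scores


def evaluate_harmonizations(
    data_by_method: dict,
    partition,
    design=None,
    shrinkage: float = 0.0,
    adjust_covariates: bool = True,
) -> EvaluationReport:
    """Compute all metrics for several harmonized versions of one dataset."""
    partition = _as_partition(partition)
    cov_diff, acc, aucs, scores = {}, {}, {}, {}
    for method, data in data_by_method.items():
        cov_diff[method] = covariance_frobenius_diff(
            data, partition, design, adjust_covariates=adjust_covariates
        )
        a, u, _ = qda_scanner_prediction(data, partition, design, shrinkage=shrinkage)
        acc[method], aucs[method] = a, u
        scores[method] = pca_scores(data)
    return EvaluationReport(
        cov_frobenius_diff=cov_diff,
        qda_accuracy=acc,
        qda_auc=aucs,
        pc_scores=scores,
        settings={"shrinkage": shrinkage, "adjust_covariates": adjust_covariates},
    )
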