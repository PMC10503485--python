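"""Nuclear-norm-penalized linked matrix factorization.

Decomposes a standardized residual matrix ``Delta`` (V x n, unit-scale noise
per scanner block) into a low-rank component shared across scanners, low-rank
components specific to each scanner, and residual noise:

    Delta = R* + [I*_1; ...; I*_M] + E

by block coordinate descent on

    0.5 * ||Delta - R* - I*||_F^2 + lambda * ||R*||_* + sum_i lambda_i * ||I*_i||_*

Each block update is the exact proximal step of the nuclear norm
(singular-value soft-thresholding at the penalty level), so the objective is
non-increasing. With the default penalties ``lambda = sqrt(V) + sqrt(n)`` and
``lambda_i = sqrt(V) + sqrt(n_i)`` the threshold dominates the largest
singular value of a unit-variance noise matrix, so pure noise is left to E.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datatypes import ScannerPartition

__all__ = [
    "PenaltyConfig",
    "LinkedDecomposition",
    "svt",
    "default_penalties",
    "objective",
    "fit_linked_decomposition",
]


@dataclass
class PenaltyConfig:
    """Nuclear-norm penalty levels and stopping rule for the factorization."""

    lambda_shared: float
    lambda_individual: np.ndarray
    max_iter: int = 500
    tol: float = 1e-6

    def __post_init__(self):
        self.lambda_individual = np.atleast_1d(np.asarray(self.lambda_individual, dtype=float))
        if self.lambda_shared <= 0 or (self.lambda_individual <= 0).any():
            raise ValueError("nuclear-norm penalties must be strictly positive")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")


@dataclass
class LinkedDecomposition:
    """Fitted components of the linked factorization."""

    shared: np.ndarray  # V x n, R*
    individual: list  # per-scanner V x n_i blocks, I*_i
    noise: np.ndarray  # V x n, E = Delta - R* - I*
    ranks: dict  # {"shared": int, "individual": [int, ...]}
    objective_trace: np.ndarray
    converged: bool
    partition: ScannerPartition = None

    def individual_full(self) -> np.ndarray:
        """Concatenated V x n individual component aligned to the data columns."""
        out = np.zeros_like(self.shared)
        for i, blk in enumerate(self.individual):
            out[:, self.partition.indices(i)] = blk
        return out


def default_penalties(
    n_features: int, n_subjects: int, sizes, max_iter: int = 500, tol: float = 1e-6
) -> PenaltyConfig:
    """Recommended penalties: sqrt(V) + sqrt(n) shared, sqrt(V) + sqrt(n_i) per scanner."""
    if n_features < 1 or n_subjects < 1:
        raise ValueError("dimensions must be positive")
    sizes = np.asarray(sizes)
    sv = np.sqrt(n_features)
    return PenaltyConfig(
        lambda_shared=sv + np.sqrt(n_subjects),
        lambda_individual=sv + np.sqrt(sizes),
        max_iter=max_iter,
        tol=tol,
    )


def _svt(matrix: np.ndarray, threshold: float):
    """Soft-threshold the singular values; returns (matrix, surviving values)."""
    U, s, Vt = np.linalg.svd(matrix, full_matrices=False)
    s = s - threshold
    k = int(np.count_nonzero(s > 0))
    if k == 0:
        return np.zeros_like(matrix), s[:0]
    return (U[:, :k] * s[:k]) @ Vt[:k], s[:k]


def svt(matrix, threshold: float) -> np.ndarray:
    """Singular-value soft-thresholding, the proximal operator of the nuclear norm.

    With ``M = U diag(d) V'``, returns ``U diag(max(d - threshold, 0)) V'``.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    out, _ = _svt(np.asarray(matrix, dtype=float), float(threshold))
    return out


def objective(delta, shared, individuals, penalties: PenaltyConfig, partition: ScannerPartition) -> float:
    """Penalized objective: half squared Frobenius misfit plus nuclear norms."""
    delta = np.asarray(delta, dtype=float)
    shared = np.asarray(shared, dtype=float)
    resid = delta - shared
    nuc = penalties.lambda_shared * np.linalg.svd(shared, compute_uv=False).sum()
    for i, blk in enumerate(individuals):
        blk = np.asarray(blk, dtype=float)
        resid[:, partition.indices(i)] -= blk
        nuc += penalties.lambda_individual[i] * np.linalg.svd(blk, compute_uv=False).sum()
    return 0.5 * float(np.sum(resid**2)) + float(nuc)


def fit_linked_decomposition(
    delta,
    partition: ScannerPartition,
    penalties: PenaltyConfig = None,
    seed=None,
) -> LinkedDecomposition:
    """Block coordinate descent for the linked factorization.

    Starting from ``R* = I*_i = 0``, alternates exact proximal updates
    ``R* <- svt(Delta - I*, lambda)`` and, per scanner,
    ``I*_i <- svt(Delta_i - R*_i, lambda_i)`` until the relative change of
    the objective drops below ``penalties.tol`` or ``max_iter`` sweeps.

    ``seed`` is accepted for interface stability but unused: all SVDs are
    deterministic.
    """
    Delta = np.asarray(delta, dtype=float)
    if not np.isfinite(Delta).all():
        raise ValueError("standardized residual matrix contains non-finite values")
    if Delta.shape[1] != partition.n_subjects:
        raise ValueError("matrix columns and partition labels are misaligned")
    M = partition.n_scanners
    if penalties is None:
        penalties = default_penalties(Delta.shape[0], Delta.shape[1], partition.sizes)
    if len(penalties.lambda_individual) != M:
        raise ValueError("one individual penalty per scanner is required")

    R = np.zeros_like(Delta)
    I_full = np.zeros_like(Delta)
    sv_R = np.zeros(0)
    sv_I = [np.zeros(0)] * M
    trace = []
    converged = False

    for _ in range(penalties.max_iter):
        R, sv_R = _svt(Delta - I_full, penalties.lambda_shared)
        for i in range(M):
            idx = partition.indices(i)
            blk, sv_i = _svt(Delta[:, idx] - R[:, idx], penalties.lambda_individual[i])
            I_full[:, idx] = blk
            sv_I[i] = sv_i
        misfit = 0.5 * float(np.sum((Delta - R - I_full) ** 2))
        nuc = penalties.lambda_shared * sv_R.sum()
        nuc += sum(penalties.lambda_individual[i] * sv_I[i].sum() for i in range(M))
        obj = misfit + float(nuc)
        trace.append(obj)
        if len(trace) > 1:
            prev = trace[-2]
            if abs(prev - obj) <= penalties.tol * max(1.0, abs(prev)):
                converged = True
                break

    if not converged:
        last = (
            abs(trace[-2] - trace[-1]) / max(1.0, abs(trace[-2])) if len(trace) > 1 else np.inf
        )
        warnings.warn(
            f"linked factorization did not converge in {penalties.max_iter} sweeps "
            f"(last relative objective change {last:.2e})",
            RuntimeWarning,
        )

    individuals = [I_full[:, partition.indices(i)].copy() for i in range(M)]
    return LinkedDecomposition(
        shared=R,
        individual=individuals,
        noise=Delta - R - I_full,
        ranks={
            "shared": int(len(sv_R)),
            "individual": [int(len(sv)) for sv in sv_I],
        },
        objective_trace=np.asarray(trace),
        converged=converged,
        partition=partition,
    )
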