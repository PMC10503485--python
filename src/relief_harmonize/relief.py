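"""RELIEF: removal of latent inter-scanner effects through factorization.

RELIEF models a features-by-subjects matrix as

    Y = A + beta X' + [Gamma_1; ...; Gamma_M] + R + [I_1; ...; I_M]
        + [delta_1 E_1; ...; delta_M E_M]

with an intercept matrix ``A``, observed covariate effects ``beta X'``,
additive scanner means ``Gamma_i`` (location effects), a low-rank latent
structure ``R`` shared by all scanners (to be preserved), low-rank latent
structures ``I_i`` specific to each scanner (to be removed), and noise whose
scale ``delta_i`` differs by scanner. The pipeline is:

(i)   two-step regression removing covariate effects and scanner means;
(ii)  per-scanner noise-scale estimation (Marčenko–Pastur median) and
      standardization of the residual blocks;
(iii) nuclear-norm-penalized linked factorization separating shared from
      scanner-specific latent variation;
(iv)  reassembly of the harmonized data

    Y_harm = A_hat + beta_hat X' + [delta_1 R*_1; ...; delta_M R*_M]
             + delta_bar E_hat,

where the shared variation is returned on its original per-scanner scale and
the noise is rescaled by the pooled scale
``delta_bar^2 = sum_i n_i delta_i^2 / n``, so noise variance is homogeneous
across scanners. Scanner means and the scanner-specific latent components are
omitted, which is precisely what harmonization removes.

Covariates of *interest* (those to be tested downstream) should not be
passed as covariates: the factorization does not force the scanner-specific
scores to be independent of them, and re-adding a fitted effect whose noise
context was altered inflates false positives. Nuisance covariates are safe
and preserved exactly.
"""

from __future__ import annotations

import numbers
from dataclasses import dataclass, field

import numpy as np

from .base import BaseHarmonizer, as_design
from .datatypes import CovariateDesign, FeatureMatrix, ScannerPartition
from .factorization import (
    LinkedDecomposition,
    PenaltyConfig,
    default_penalties,
    fit_linked_decomposition,
)
from .noise_scale import NoiseScales, estimate_noise_scales, standardize_blocks
from .preprocess import TwoStepRegressionFit, two_step_regression

__all__ = ["HarmonizedDataset", "reconstruct_harmonized", "relief_harmonize", "ReliefHarmonizer"]


@dataclass
class HarmonizedDataset:
    """A harmonized V x n matrix together with its additive components.

    ``values`` equals the sum of the ``components`` matrices to machine
    precision; ``provenance`` records the method settings and fitted scales
    needed to reproduce the run.
    """

    values: np.ndarray
    components: dict
    method: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        total = sum(self.components.values())
        if not np.allclose(self.values, total, atol=1e-8 * max(1.0, float(np.abs(self.values).max()))):
            raise ValueError("harmonized values do not equal the sum of their components")


def reconstruct_harmonized(
    fit: TwoStepRegressionFit,
    decomp: LinkedDecomposition,
    scales: NoiseScales,
) -> HarmonizedDataset:
    """Assemble harmonized data from the fitted RELIEF components.

    Re-adds intercepts and covariate effects, rescales the shared latent
    blocks by their scanner's delta_i (original scale), and rescales the
    noise by the pooled delta. Scanner means and the scanner-specific latent
    components are dropped. If feature scaling was enabled in preprocessing
    it is inverted last.
    """
    partition = fit.partition
    shared = decomp.shared * scales.delta[partition.scanner_index]
    noise = decomp.noise * scales.pooled_delta
    rescale = fit.feature_scales[:, None]
    shared = shared * rescale
    noise = noise * rescale
    intercepts = np.broadcast_to(fit.intercepts[:, None], shared.shape).copy()
    covariate_effects = (
        fit.coefficients @ fit.design.values.T
        if fit.design.n_covariates
        else np.zeros_like(shared)
    )
    components = {
        "intercepts": intercepts,
        "covariate_effects": covariate_effects,
        "shared_variation": shared,
        "noise": noise,
    }
    values = intercepts + covariate_effects + shared + noise
    provenance = {
        "delta": scales.delta.tolist(),
        "pooled_delta": scales.pooled_delta,
        "ranks": decomp.ranks,
        "converged": bool(decomp.converged),
        "n_iterations": int(len(decomp.objective_trace)),
        "feature_scaling": bool(not np.allclose(fit.feature_scales, 1.0)),
    }
    return HarmonizedDataset(values=values, components=components, method="relief", provenance=provenance)


def _resolve_penalties(V, n, partition, lambda_shared, lambda_individual, max_iter, tol):
    base = default_penalties(V, n, partition.sizes, max_iter=max_iter, tol=tol)
    lam = base.lambda_shared if lambda_shared is None else float(lambda_shared)
    if lambda_individual is None:
        lam_i = base.lambda_individual
    elif isinstance(lambda_individual, numbers.Real):
        lam_i = np.full(partition.n_scanners, float(lambda_individual))
    else:
        lam_i = np.asarray(lambda_individual, dtype=float)
    return PenaltyConfig(lambda_shared=lam, lambda_individual=lam_i, max_iter=max_iter, tol=tol)


def _relief_pipeline(
    values: np.ndarray,
    design: CovariateDesign,
    partition: ScannerPartition,
    *,
    scale_features: bool = False,
    lambda_shared=None,
    lambda_individual=None,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed=None,
):
    fit = two_step_regression(values, design, partition, scale=scale_features)
    scales = estimate_noise_scales(fit.residuals, partition)
    delta_matrix = standardize_blocks(fit.residuals, partition, scales)
    penalties = _resolve_penalties(
        values.shape[0], values.shape[1], partition,
        lambda_shared, lambda_individual, max_iter, tol,
    )
    decomp = fit_linked_decomposition(delta_matrix, partition, penalties, seed=seed)
    dataset = reconstruct_harmonized(fit, decomp, scales)
    dataset.provenance.update(
        {
            "lambda_shared": penalties.lambda_shared,
            "lambda_individual": penalties.lambda_individual.tolist(),
            "tol": penalties.tol,
            "max_iter": penalties.max_iter,
            "scale_features": bool(scale_features),
        }
    )
    return fit, scales, decomp, dataset


def relief_harmonize(data, design=None, partition=None, **options) -> HarmonizedDataset:
    """Harmonize a V x n feature matrix with RELIEF.

    Parameters
    ----------
    data : FeatureMatrix or ndarray of shape (V, n)
    design : CovariateDesign or ndarray (n, q), optional
        Nuisance covariates whose effects are preserved exactly. Do not pass
        covariates of interest.
    partition : ScannerPartition or label array of shape (n,)
    options : scale_features, lambda_shared, lambda_individual, max_iter,
        tol, seed — see :class:`ReliefHarmonizer`.
    """
    values = data.values if isinstance(data, FeatureMatrix) else np.asarray(data, dtype=float)
    if partition is None:
        raise ValueError("a scanner partition (or label vector) is required")
    if not isinstance(partition, ScannerPartition):
        partition = ScannerPartition(np.asarray(partition))
    design = as_design(design, values.shape[1])
    *_, dataset = _relief_pipeline(values, design, partition, **options)
    return dataset


class ReliefHarmonizer(BaseHarmonizer):
    """Scanner-effect harmonization by linked low-rank factorization.

    Removes additive scanner means, scanner-specific latent (low-rank)
    variation, and homogenises noise variance across scanners, while
    preserving covariate effects and latent variation shared by all
    scanners.

    Parameters
    ----------
    scale_features : bool, default False
        Divide each feature's residuals by their standard deviation before
        noise estimation and factorization (inverted exactly afterwards).
        Useful when feature variances span orders of magnitude.
    lambda_shared : float, optional
        Nuclear-norm penalty for the shared component; defaults to
        ``sqrt(V) + sqrt(n)``.
    lambda_individual : float or array of shape (M,), optional
        Penalties for the scanner-specific components; default
        ``sqrt(V) + sqrt(n_i)``.
    max_iter : int, default 500
    tol : float, default 1e-6
        Relative objective-change stopping tolerance of the block
        coordinate descent.
    seed : int, optional
        Accepted for interface stability; the solver is deterministic.

    Attributes
    ----------
    harmonized_ : ndarray (n_subjects, n_features)
    dataset_ : HarmonizedDataset (V x n orientation, with components)
    regression_fit_ : TwoStepRegressionFit
    noise_scales_ : NoiseScales
    decomposition_ : LinkedDecomposition
    """

    def __init__(
        self,
        scale_features: bool = False,
        lambda_shared=None,
        lambda_individual=None,
        max_iter: int = 500,
        tol: float = 1e-6,
        seed=None,
    ):
        self.scale_features = scale_features
        self.lambda_shared = lambda_shared
        self.lambda_individual = lambda_individual
        self.max_iter = max_iter
        self.tol = tol
        self.seed = seed

    def _harmonize(self, values, design, partition):
        fit, scales, decomp, dataset = _relief_pipeline(
            values,
            design,
            partition,
            scale_features=self.scale_features,
            lambda_shared=self.lambda_shared,
            lambda_individual=self.lambda_individual,
            max_iter=self.max_iter,
            tol=self.tol,
            seed=self.seed,
        )
        self.regression_fit_ = fit
        self.noise_scales_ = scales
        self.decomposition_ = decomp
        return dataset
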