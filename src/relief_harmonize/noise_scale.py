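"""Per-scanner noise-scale estimation via the Marčenko–Pastur median.

For a pure-noise V x n_i matrix with i.i.d. entries of standard deviation
delta, the median singular value concentrates at
``delta * sqrt(max(V, n_i) * mu_beta)`` where ``mu_beta`` is the median of
the Marčenko–Pastur eigenvalue distribution with aspect ratio
``beta = min(V, n_i) / max(V, n_i)`` (unit-variance convention, support
``[(1 - sqrt(beta))^2, (1 + sqrt(beta))^2]``). Inverting this relation gives
a noise-level estimate that is robust to a few large signal singular values
because it only uses the median.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.integrate import quad
from scipy.linalg import svdvals
from scipy.optimize import brentq

from .datatypes import ScannerPartition

__all__ = ["NoiseScales", "mp_median", "estimate_delta", "estimate_noise_scales", "standardize_blocks"]


@dataclass
class NoiseScales:
    """Per-scanner noise scales and their pooled (weighted RMS) value."""

    delta: np.ndarray  # (M,) per-scanner delta_i
    pooled_delta: float  # sqrt(sum n_i delta_i^2 / n)
    mp_medians: np.ndarray  # (M,) MP medians used per scanner


@lru_cache(maxsize=256)
def mp_median(aspect_ratio: float) -> float:
    """Median of the Marčenko–Pastur distribution with ratio ``beta``.

    Computed by adaptive quadrature of the MP density and bisection on the
    CDF. The density is integrated after the substitution ``x = a + u^2``,
    which removes both the square-root edge at ``a`` and the ``1/x``
    singularity when ``beta = 1``. Relative tolerance ~1e-10.
    """
    beta = float(aspect_ratio)
    if not 0.0 < beta <= 1.0:
        raise ValueError(f"aspect ratio must be in (0, 1], got {beta}")
    sb = np.sqrt(beta)
    a, b = (1.0 - sb) ** 2, (1.0 + sb) ** 2
    if beta < 1e-10:  # point mass at 1 in the beta -> 0 limit
        return 1.0

    def transformed_density(u):
        x = a + u * u
        return np.sqrt(max((b - x) * (x - a), 0.0)) / (np.pi * beta * x) * u

    def cdf(x):
        val, _ = quad(transformed_density, 0.0, np.sqrt(x - a), epsabs=1e-12, epsrel=1e-12, limit=200)
        return val

    lo = a + 1e-12 * (b - a)
    hi = b - 1e-12 * (b - a)
    return float(brentq(lambda x: cdf(x) - 0.5, lo, hi, xtol=1e-13, rtol=1e-12))


def estimate_delta(residual_block) -> float:
    """Noise scale of one scanner's residual block.

    ``delta_hat = median(singular values) / sqrt(max(V, n_i) * mu_beta)``.
    On a unit-variance i.i.d. noise block this returns approximately 1,
    which is the normalisation the standardized matrix requires.
    """
    block = np.asarray(residual_block, dtype=float)
    if block.ndim != 2 or min(block.shape) < 2:
        raise ValueError(f"residual block must be at least 2 x 2, got shape {block.shape}")
    s = svdvals(block)
    if s.max(initial=0.0) <= 0.0:
        raise ValueError("degenerate (all-zero) residual block; noise scale undefined")
    lo, hi = sorted(block.shape)
    beta = lo / hi
    return float(np.median(s) / np.sqrt(hi * mp_median(beta)))


def estimate_noise_scales(residuals, partition: ScannerPartition) -> NoiseScales:
    """Estimate delta_i for every scanner block of a residual matrix."""
    blocks = partition.blocks(np.asarray(residuals, dtype=float))
    delta = np.array([estimate_delta(blk) for blk in blocks])
    medians = np.array([mp_median(min(b.shape) / max(b.shape)) for b in blocks])
    pooled = float(np.sqrt(np.sum(partition.sizes * delta**2) / partition.n_subjects))
    return NoiseScales(delta=delta, pooled_delta=pooled, mp_medians=medians)


def standardize_blocks(residuals, partition: ScannerPartition, scales: NoiseScales) -> np.ndarray:
    """Divide each scanner block by its delta_i, homogenising noise variance."""
    R = np.asarray(residuals, dtype=float)
    if R.shape[1] != partition.n_subjects:
        raise ValueError("residual columns and partition labels are misaligned")
    if len(scales.delta) != partition.n_scanners:
        raise ValueError("noise scales and partition are misaligned")
    return R / scales.delta[partition.scanner_index]
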