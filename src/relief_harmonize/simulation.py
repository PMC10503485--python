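"""Synthetic multi-scanner data generators and the permutation FWER/power protocol.

Two generative designs are provided:

* :func:`simulate_linked_factor_design` plants the full additive model the
  harmonizer assumes — covariate effects, shared location effects, a rank-3
  shared latent structure, rank-3 scanner-specific latent structures whose
  strength is controlled by a multiplier ``c``, and scanner-heteroscedastic
  Gaussian noise. It is the self-contained test bed for false-positive
  calibration and power.
* :func:`simulate_pc_shift_design` plants covariance scanner effects as
  rank-``L`` eigenvalue shifts of a base correlation matrix, with
  inverse-gamma multiplicative scale effects — the regime the PC-score
  comparator targets. The base correlation matrix is user-supplied or a
  synthetic random correlation matrix with an exponential-decay spectrum.

:func:`permutation_fwer_power` wraps the full study loop: simulate, spike a
binary covariate of interest into a random feature subset, harmonize with
any of the methods (the covariate of interest excluded from the design by
default), test every feature with a two-sample t statistic, and control the
family-wise error rate at level alpha with Westfall–Young single-step max-|T|
permutation p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .comparators import adjres_harmonize, combat_harmonize, covbat_harmonize
from .datatypes import CovariateDesign, ScannerPartition
from .relief import relief_harmonize

__all__ = [
    "LinkedFactorSimConfig",
    "PCShiftSimConfig",
    "SpikeConfig",
    "SimulatedDataset",
    "FwerPowerResult",
    "simulate_linked_factor_design",
    "simulate_pc_shift_design",
    "synthetic_correlation",
    "spike_effects",
    "max_t_test",
    "permutation_fwer_power",
]


@dataclass
class LinkedFactorSimConfig:
    """Planted low-rank two-scanner design.

    Defaults are the standard study conditions: two scanners of 50 subjects,
    100 features, four nuisance covariates with AR(1) correlation 0.2,
    rank-3 shared and rank-3 per-scanner latent components, location effects
    N(0, 1.5^2) shared across scanners, noise scales Uniform(1, 1.5).
    ``individual_strength`` is the multiplier ``c`` of the scanner-specific
    latent component (0 switches it off).
    """

    n_per_scanner: tuple = (50, 50)
    n_features: int = 100
    n_nuisance: int = 4
    rank_shared: int = 3
    rank_individual: int = 3
    individual_strength: float = 0.0
    location_sd: float = 1.5
    scale_range: tuple = (1.0, 1.5)
    ar1_rho: float = 0.2
    seed: object = None


@dataclass
class PCShiftSimConfig:
    """Covariance-shift design: MVN errors with rank-L eigenvalue shifts.

    Scanner i draws errors from ``MVN(0, S + c_i * sum_{l<=L} lam_l psi_l
    psi_l')`` where ``(lam_l, psi_l)`` is the eigendecomposition of the base
    correlation matrix ``S``; scale effects are drawn per feature from
    inverse-gamma laws. ``shift_rank = 0`` (or both magnitudes 0) gives
    homogeneous covariances.
    """

    n_per_scanner: tuple = (172, 179)
    n_features: int = 72
    base_mean: np.ndarray = None
    correlation: np.ndarray = None
    shift_rank: int = 0
    shift_magnitudes: tuple = (-0.75, 0.75)
    location_sd: float = 0.1
    scale_ig: tuple = ((46.0, 50.0), (51.0, 50.0))
    spectrum_decay: float = 0.8
    seed: object = None


@dataclass
class SpikeConfig:
    """Covariate-of-interest effect spiked into a random feature subset."""

    effect_size: float = 0.0
    fraction: float = 0.2
    z: np.ndarray = None
    seed: object = None

    def __post_init__(self):
        if self.effect_size < 0:
            raise ValueError("effect size must be non-negative")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("spiked fraction must be in [0, 1]")


@dataclass
class SimulatedDataset:
    """Generated data plus the planted truth for recovery checks."""

    data: np.ndarray  # V x n
    covariates: CovariateDesign
    partition: ScannerPartition
    truth: dict
    config: object


@dataclass
class FwerPowerResult:
    """Outcome of a repeated-dataset permutation study."""

    n_datasets: int
    n_permutations: int
    alpha: float
    fwer: float = None
    fwer_ci: tuple = None
    power: float = None
    power_ci: tuple = None
    any_rejection: np.ndarray = None
    detected_fraction: np.ndarray = None


def _rng(seed):
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _truncated_reconstruction(matrix: np.ndarray, rank: int) -> np.ndarray:
    """Rank-r truncated SVD reconstruction (the leading principal components)."""
    U, s, Vt = np.linalg.svd(matrix, full_matrices=False)
    return (U[:, :rank] * s[:rank]) @ Vt[:rank]


def simulate_linked_factor_design(
    config: LinkedFactorSimConfig = None, rng=None
) -> SimulatedDataset:
    """Draw one dataset from the planted linked low-rank model."""
    config = config or LinkedFactorSimConfig()
    rng = _rng(config.seed if rng is None else rng)
    sizes = tuple(int(k) for k in config.n_per_scanner)
    V, n, q = config.n_features, sum(sizes), config.n_nuisance
    M = len(sizes)

    labels = np.repeat([f"scanner{i + 1}" for i in range(M)], sizes)
    partition = ScannerPartition(labels)

    intercept_rows = rng.standard_normal(V)
    A = np.broadcast_to(intercept_rows[:, None], (V, n)).copy()
    if q:
        beta = rng.standard_normal((V, q))
        ar1 = config.ar1_rho ** np.abs(np.subtract.outer(np.arange(q), np.arange(q)))
        X = rng.multivariate_normal(np.zeros(q), ar1, size=n)
        covariate_effects = beta @ X.T
    else:
        beta = np.zeros((V, 0))
        X = np.empty((n, 0))
        covariate_effects = np.zeros((V, n))

    gamma = rng.normal(0.0, config.location_sd, size=V)  # shared across scanners
    Gamma = np.broadcast_to(gamma[:, None], (V, n)).copy()

    R = _truncated_reconstruction(rng.standard_normal((V, n)), config.rank_shared)
    I_full = np.zeros((V, n))
    for i in range(M):
        idx = partition.indices(i)
        I_full[:, idx] = _truncated_reconstruction(
            rng.standard_normal((V, len(idx))), config.rank_individual
        )
    I_full *= config.individual_strength

    delta = rng.uniform(*config.scale_range, size=M)
    E = rng.standard_normal((V, n))
    noise = E * delta[partition.scanner_index]

    Y = A + covariate_effects + Gamma + R + I_full + noise
    truth = {
        "intercepts": intercept_rows,
        "beta": beta,
        "gamma": gamma,
        "shared": R,
        "individual": I_full,
        "delta": delta,
        "noise": noise,
    }
    return SimulatedDataset(
        data=Y,
        covariates=CovariateDesign(X) if q else CovariateDesign.empty(n),
        partition=partition,
        truth=truth,
        config=config,
    )


def synthetic_correlation(n_features: int, decay: float = 0.8, rng=None) -> np.ndarray:
    """Random correlation matrix with a geometric eigenvalue spectrum.

    Eigenvalues proportional to ``decay**l`` (normalised to sum to V, as a
    correlation matrix requires) are combined with random eigenvectors via
    Givens rotations, emulating the strongly structured correlation of
    tract-level imaging features.
    """
    rng = _rng(rng)
    eigs = decay ** np.arange(n_features)
    eigs = eigs * (n_features / eigs.sum())
    return stats.random_correlation.rvs(eigs, random_state=rng, tol=1e-10)


def simulate_pc_shift_design(config: PCShiftSimConfig = None, rng=None) -> SimulatedDataset:
    """Draw one dataset with rank-L covariance scanner shifts."""
    config = config or PCShiftSimConfig()
    rng = _rng(config.seed if rng is None else rng)
    sizes = tuple(int(k) for k in config.n_per_scanner)
    V, n = config.n_features, sum(sizes)
    M = len(sizes)
    if len(config.shift_magnitudes) != M or len(config.scale_ig) != M:
        raise ValueError("one shift magnitude and one IG law per scanner are required")

    S = (
        np.asarray(config.correlation, dtype=float)
        if config.correlation is not None
        else synthetic_correlation(V, config.spectrum_decay, rng)
    )
    if S.shape != (V, V) or not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric V x V")
    evals, evecs = np.linalg.eigh(S)
    if evals.min() < -1e-8 * max(1.0, evals.max()):
        raise ValueError("base correlation matrix is not positive semidefinite")
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    L = int(config.shift_rank)
    if not 0 <= L <= V:
        raise ValueError(f"shift rank must be in [0, {V}]")

    alpha = (
        np.asarray(config.base_mean, dtype=float)
        if config.base_mean is not None
        else rng.uniform(0.3, 0.7, size=V)
    )
    labels = np.repeat([f"scanner{i + 1}" for i in range(M)], sizes)
    partition = ScannerPartition(labels)

    shift = (evecs[:, :L] * evals[:L]) @ evecs[:, :L].T if L else np.zeros((V, V))
    Y = np.empty((V, n))
    gamma = np.empty((M, V))
    delta = np.empty((M, V))
    covariances = []
    for i in range(M):
        cov_i = S + config.shift_magnitudes[i] * shift
        lam_min = np.linalg.eigvalsh(cov_i).min()
        if lam_min < -1e-8 * max(1.0, np.abs(cov_i).max()):
            raise ValueError(
                f"shifted covariance for scanner {i + 1} is not positive semidefinite "
                f"(smallest eigenvalue {lam_min:.3g}); reduce |shift magnitude| or L"
            )
        covariances.append(cov_i)
        gamma[i] = rng.normal(0.0, config.location_sd, size=V)
        a, scale = config.scale_ig[i]
        delta[i] = stats.invgamma.rvs(a, scale=scale, size=V, random_state=rng)
        eps = rng.multivariate_normal(np.zeros(V), cov_i, size=sizes[i], method="eigh")
        idx = partition.indices(i)
        Y[:, idx] = alpha[:, None] + gamma[i][:, None] + delta[i][:, None] * eps.T

    truth = {
        "base_mean": alpha,
        "correlation": S,
        "covariances": covariances,
        "gamma": gamma,
        "delta": delta,
        "shift_rank": L,
    }
    return SimulatedDataset(
        data=Y,
        covariates=CovariateDesign.empty(n),
        partition=partition,
        truth=truth,
        config=config,
    )


def spike_effects(dataset: SimulatedDataset, spike: SpikeConfig, rng=None) -> SimulatedDataset:
    """Add ``tau * z`` to a random fraction of feature rows.

    Returns a new dataset; the spiked feature set, the binary covariate and
    the effect size are recorded in ``truth``.
    """
    rng = _rng(spike.seed if rng is None else rng)
    V, n = dataset.data.shape
    z = spike.z if spike.z is not None else rng.integers(0, 2, size=n)
    z = np.asarray(z, dtype=float).reshape(-1)
    if z.size != n or not np.isin(z, (0.0, 1.0)).all():
        raise ValueError("z must be a binary vector of length n")
    n_spiked = int(round(spike.fraction * V))
    spiked = np.sort(rng.choice(V, size=n_spiked, replace=False))
    data = dataset.data.copy()
    data[spiked] += spike.effect_size * z
    truth = dict(dataset.truth)
    truth.update({"spiked_features": spiked, "z": z, "effect_size": spike.effect_size})
    return SimulatedDataset(
        data=data,
        covariates=dataset.covariates,
        partition=dataset.partition,
        truth=truth,
        config=dataset.config,
    )


def _two_sample_t(Y: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t per feature row, vectorised over label columns.

    ``Z`` is (n,) or (n, B) of 0/1 labels; returns (V,) or (V, B).
    """
    squeeze = Z.ndim == 1
    Z = np.atleast_2d(Z.T).T.astype(float)
    n = Y.shape[1]
    n1 = Z.sum(axis=0)
    n0 = n - n1
    s1 = Y @ Z
    s0 = Y.sum(axis=1)[:, None] - s1
    m1, m0 = s1 / n1, s0 / n0
    q1 = (Y**2) @ Z
    q0 = (Y**2).sum(axis=1)[:, None] - q1
    ss = q1 - n1 * m1**2 + q0 - n0 * m0**2
    var_pooled = ss / (n - 2)
    t = (m1 - m0) / np.sqrt(var_pooled * (1.0 / n1 + 1.0 / n0))
    return t[:, 0] if squeeze else t


def max_t_test(values: np.ndarray, z: np.ndarray, n_permutations: int = 1000,
               alpha: float = 0.05, rng=None, nuisance: CovariateDesign = None):
    """Westfall–Young single-step max-|T| permutation test across features.

    Returns ``(reject, p_values, t_observed)``. Feature v is rejected when
    ``p_v = (1 + #{b : max_b >= |t_v|}) / (B + 1) <= alpha``, which controls
    the family-wise error rate at alpha.

    When ``nuisance`` is given, its effects (plus an intercept) are regressed
    out of every feature before the two-sample t statistics are formed, the
    standard adjustment when nuisance covariates are present.
    """
    if n_permutations < 100:
        warnings.warn(
            f"{n_permutations} permutations give an unstable max-|T| quantile; "
            "use at least a few hundred",
            RuntimeWarning,
        )
    rng = _rng(rng)
    z = np.asarray(z, dtype=float).reshape(-1)
    values = np.asarray(values, dtype=float)
    if nuisance is not None and nuisance.n_covariates:
        D = nuisance.with_intercept()
        coef, *_ = np.linalg.lstsq(D, values.T, rcond=None)
        values = values - (D @ coef).T
    t_obs = _two_sample_t(values, z)
    perms = rng.permuted(np.tile(z, (n_permutations, 1)), axis=1).T  # n x B
    t_perm = _two_sample_t(values, perms)
    maxes = np.abs(t_perm).max(axis=0)
    exceed = (maxes[None, :] >= np.abs(t_obs)[:, None]).sum(axis=1)
    p_values = (1.0 + exceed) / (n_permutations + 1.0)
    return p_values <= alpha, p_values, t_obs


_METHODS = {
    "relief": relief_harmonize,
    "combat": combat_harmonize,
    "covbat": covbat_harmonize,
    "adjres": adjres_harmonize,
    "none": None,
}


def _resolve_harmonizer(harmonizer):
    """Accept a method name or an estimator; return callable(values, design, partition)."""
    if isinstance(harmonizer, str):
        key = harmonizer.lower()
        if key not in _METHODS:
            raise ValueError(f"unknown method {harmonizer!r}; choose from {sorted(_METHODS)}")
        func = _METHODS[key]
        if func is None:
            return lambda values, design, partition: values
        return lambda values, design, partition: func(values, design, partition).values
    if hasattr(harmonizer, "fit") and hasattr(harmonizer, "get_params"):
        from sklearn.base import clone

        def run(values, design, partition):
            est = clone(harmonizer)
            est.fit(values.T, batch=partition, covariates=design)
            return est.harmonized_.T

        return run
    raise TypeError("harmonizer must be a method name or an sklearn-style estimator")


def _simulate(config, rng):
    if isinstance(config, LinkedFactorSimConfig):
        return simulate_linked_factor_design(config, rng=rng)
    if isinstance(config, PCShiftSimConfig):
        return simulate_pc_shift_design(config, rng=rng)
    raise TypeError(f"unsupported simulation config type {type(config).__name__}")


def _clopper_pearson(k: int, n: int, level: float = 0.95):
    lo = stats.beta.ppf((1 - level) / 2, k, n - k + 1) if k > 0 else 0.0
    hi = stats.beta.ppf(1 - (1 - level) / 2, k + 1, n - k) if k < n else 1.0
    return float(lo), float(hi)


def permutation_fwer_power(
    harmonizer,
    config,
    spike: SpikeConfig = None,
    n_datasets: int = 100,
    n_permutations: int = 1000,
    alpha: float = 0.05,
    include_covariate_of_interest: bool = False,
    adjust_covariates: bool = True,
    seed=None,
) -> FwerPowerResult:
    """Repeated-dataset permutation study of FWER (null) or power (spiked).

    For each dataset: simulate, draw a fresh binary covariate of interest
    ``z``, optionally spike ``tau * z`` into a random feature subset,
    harmonize (``z`` excluded from the harmonization design unless
    ``include_covariate_of_interest`` — the configuration known to inflate
    false positives), and run the max-|T| permutation test of the harmonized
    features against ``z`` at level ``alpha``. With ``adjust_covariates``
    (the default) the nuisance covariates are regressed out of the
    harmonized data before the per-feature statistics, the standard
    confounder adjustment.

    Returns the empirical FWER (fraction of datasets with any rejection,
    with a Clopper–Pearson 95% interval) for null runs, and the mean
    detected fraction of spiked features (with a normal-approximation 95%
    interval over datasets) for spiked runs.
    """
    run = _resolve_harmonizer(harmonizer)
    children = np.random.SeedSequence(seed).spawn(n_datasets)
    spiked_run = spike is not None and spike.effect_size > 0 and spike.fraction > 0
    any_rejection = np.zeros(n_datasets, dtype=bool)
    detected = np.full(n_datasets, np.nan)

    for d, child in enumerate(children):
        rng = np.random.default_rng(child)
        dataset = _simulate(config, rng)
        n = dataset.partition.n_subjects
        z = rng.integers(0, 2, size=n)
        while z.min() == z.max():  # both groups must be populated
            z = rng.integers(0, 2, size=n)
        if spiked_run:
            dataset = spike_effects(dataset, replace(spike, z=z, seed=None), rng=rng)
        design = dataset.covariates
        if include_covariate_of_interest:
            design = design.add_column(z, "z")
        harmonized = run(dataset.data, design, dataset.partition)
        reject, _, _ = max_t_test(
            harmonized, z, n_permutations=n_permutations, alpha=alpha, rng=rng,
            nuisance=dataset.covariates if adjust_covariates else None,
        )
        any_rejection[d] = bool(reject.any())
        if spiked_run:
            spiked = dataset.truth["spiked_features"]
            detected[d] = reject[spiked].mean() if len(spiked) else np.nan

    result = FwerPowerResult(
        n_datasets=n_datasets,
        n_permutations=n_permutations,
        alpha=alpha,
        any_rejection=any_rejection,
    )
    if spiked_run:
        frac = detected[~np.isnan(detected)]
        power = float(frac.mean())
        half = 1.96 * float(frac.std(ddof=1)) / np.sqrt(len(frac)) if len(frac) > 1 else 0.0
        result.power = power
        result.power_ci = (max(0.0, power - half), min(1.0, power + half))
        result.detected_fraction = detected
    else:
        k = int(any_rejection.sum())
        result.fwer = k / n_datasets
        result.fwer_ci = _clopper_pearson(k, n_datasets)
    return result
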