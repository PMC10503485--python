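"""Reference harmonization methods: AdjRes, ComBat, and CovBat.

AdjRes removes per-feature scanner means only. ComBat additionally rescales
per-feature, per-scanner residual variance to the pooled variance, with
parametric empirical-Bayes shrinkage of the location/scale parameters across
features (normal prior on locations, inverse-gamma on variances,
method-of-moments hyperparameters, iterated conditional updates). CovBat
runs ComBat, then applies a second location/scale adjustment to the leading
principal-component scores of the ComBat residual covariance, targeting
covariance heterogeneity that survives the univariate adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .base import BaseHarmonizer, as_design
from .datatypes import CovariateDesign, FeatureMatrix, ScannerPartition
from .preprocess import two_step_regression
from .relief import HarmonizedDataset

__all__ = [
    "CombatFit",
    "CovbatFit",
    "adjres_harmonize",
    "combat_harmonize",
    "covbat_harmonize",
    "AdjResHarmonizer",
    "ComBatHarmonizer",
    "CovBatHarmonizer",
]


@dataclass
class CombatFit:
    """Fitted ComBat parameters.

    ``gamma_star`` / ``phi_star`` are the (possibly shrunken) additive and
    multiplicative scanner effects on the standardized scale, V x M.
    """

    gamma_star: np.ndarray
    phi_star: np.ndarray
    gamma_hat: np.ndarray
    delta2_hat: np.ndarray
    hyperparams: dict
    pooled_feature_means: np.ndarray  # grand mean per feature
    pooled_feature_vars: np.ndarray
    empirical_bayes: bool


@dataclass
class CovbatFit:
    combat_stage: CombatFit
    pc_loadings: np.ndarray  # V x V eigenvectors of the ComBat-residual covariance
    eigenvalues: np.ndarray
    n_pcs: int
    variance_retained: float
    score_stage: CombatFit


def _values(data):
    return data.values if isinstance(data, FeatureMatrix) else np.asarray(data, dtype=float)


def _as_partition(partition):
    if isinstance(partition, ScannerPartition):
        return partition
    return ScannerPartition(np.asarray(partition))


def adjres_harmonize(data, design=None, partition=None) -> HarmonizedDataset:
    """Remove scanner-specific feature means; variances are left untouched."""
    Y = _values(data)
    partition = _as_partition(partition)
    design = as_design(design, Y.shape[1])
    fit = two_step_regression(Y, design, partition, scale=False)
    fitted = fit.fitted_mean()
    intercepts = np.broadcast_to(fit.intercepts[:, None], Y.shape).copy()
    components = {
        "intercepts": intercepts,
        "covariate_effects": fitted - intercepts,
        "residuals": fit.residuals,
    }
    return HarmonizedDataset(
        values=fitted + fit.residuals,
        components=components,
        method="adjres",
        provenance={"n_scanners": partition.n_scanners},
    )


def _eb_shrink(s_block, g_hat, d_hat, n_i, conv=1e-8, max_iter=1000):
    """Iterated conditional posterior updates for one scanner's parameters."""
    g_bar = g_hat.mean()
    t2 = g_hat.var(ddof=1)
    m = d_hat.mean()
    s2 = d_hat.var(ddof=1)
    if s2 <= 0 or t2 <= 0:
        raise ValueError("degenerate spread of location/scale estimates across features; "
                         "empirical Bayes needs feature-to-feature variability (or disable EB)")
    a_prior = (2 * s2 + m**2) / s2
    b_prior = (m * s2 + m**3) / s2
    g_new, d_new = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_old, d_old = g_new, d_new
        g_new = (n_i * t2 * g_hat + d_old * g_bar) / (n_i * t2 + d_old)
        sum2 = ((s_block - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (0.5 * sum2 + b_prior) / (n_i / 2.0 + a_prior - 1.0)
        change = max(
            np.max(np.abs(g_new - g_old) / (np.abs(g_old) + 1e-12)),
            np.max(np.abs(d_new - d_old) / (np.abs(d_old) + 1e-12)),
        )
        if change < conv:
            break
    hyper = {"gamma_bar": float(g_bar), "tau2": float(t2), "a_prior": float(a_prior), "b_prior": float(b_prior)}
    return g_new, d_new, hyper


def _combat_core(
    values: np.ndarray,
    design: CovariateDesign,
    partition: ScannerPartition,
    empirical_bayes: bool = True,
    var_ddof: int = 0,
    conv: float = 1e-8,
):
    """Location/scale ComBat on a V x n matrix; returns (dataset, CombatFit).

    Standardization follows the cited ComBat algorithm: the regression
    includes the batch indicators, the grand mean is the sample-size-weighted
    average of the batch intercepts, and residual variance is pooled over all
    subjects. ``var_ddof`` sets the divisor of the within-batch variance of
    the standardized data (0: population convention, making single-batch
    ComBat an exact no-op; 1: the sva/R convention).
    """
    Y = values
    V, n = Y.shape
    M = partition.n_scanners
    sizes = partition.sizes
    B = np.zeros((n, M))
    B[np.arange(n), partition.scanner_index] = 1.0
    D = np.column_stack([B, design.values]) if design.n_covariates else B
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise ValueError(
            "covariates are confounded with scanner labels (design including batch "
            "indicators is rank deficient); drop the offending covariates"
        )
    B_hat, *_ = np.linalg.lstsq(D, Y.T, rcond=None)  # (M+q) x V
    grand_mean = (sizes / n) @ B_hat[:M]
    resid = Y - (D @ B_hat).T
    var_pooled = (resid**2).mean(axis=1)
    if (var_pooled <= 0).any():
        bad = np.flatnonzero(var_pooled <= 0).tolist()
        raise ValueError(f"features with zero pooled residual variance: rows {bad}")
    stand_mean = grand_mean[:, None] + (
        (design.values @ B_hat[M:]).T if design.n_covariates else 0.0
    )
    sd = np.sqrt(var_pooled)[:, None]
    s_data = (Y - stand_mean) / sd

    gamma_hat = np.empty((V, M))
    delta2_hat = np.empty((V, M))
    for i in range(M):
        blk = s_data[:, partition.indices(i)]
        gamma_hat[:, i] = blk.mean(axis=1)
        delta2_hat[:, i] = blk.var(axis=1, ddof=var_ddof)
        if (delta2_hat[:, i] <= 0).any():
            bad = np.flatnonzero(delta2_hat[:, i] <= 0).tolist()
            raise ValueError(
                f"constant feature(s) within scanner {partition.scanner_ids[i]!r}: rows {bad}"
            )

    hyper = {}
    if empirical_bayes:
        gamma_star = np.empty_like(gamma_hat)
        delta2_star = np.empty_like(delta2_hat)
        for i in range(M):
            blk = s_data[:, partition.indices(i)]
            g, d, h = _eb_shrink(blk, gamma_hat[:, i], delta2_hat[:, i], sizes[i], conv=conv)
            gamma_star[:, i], delta2_star[:, i] = g, d
            hyper[str(partition.scanner_ids[i])] = h
    else:
        gamma_star, delta2_star = gamma_hat.copy(), delta2_hat.copy()

    idx = partition.scanner_index
    adj = (s_data - gamma_star[:, idx]) / np.sqrt(delta2_star[:, idx])
    harmonized = adj * sd + stand_mean

    intercepts = np.broadcast_to(grand_mean[:, None], Y.shape).copy()
    covariate_effects = (
        (design.values @ B_hat[M:]).T if design.n_covariates else np.zeros_like(Y)
    )
    components = {
        "intercepts": intercepts,
        "covariate_effects": covariate_effects,
        "residuals": adj * sd,
    }
    fit = CombatFit(
        gamma_star=gamma_star,
        phi_star=np.sqrt(delta2_star),
        gamma_hat=gamma_hat,
        delta2_hat=delta2_hat,
        hyperparams=hyper,
        pooled_feature_means=grand_mean,
        pooled_feature_vars=var_pooled,
        empirical_bayes=empirical_bayes,
    )
    dataset = HarmonizedDataset(
        values=harmonized,
        components=components,
        method="combat",
        provenance={"empirical_bayes": bool(empirical_bayes), "var_ddof": int(var_ddof)},
    )
    return dataset, fit


def combat_harmonize(
    data, design=None, partition=None, eb: bool = True, var_ddof: int = 0
) -> HarmonizedDataset:
    """Location/scale harmonization with optional empirical-Bayes shrinkage."""
    Y = _values(data)
    partition = _as_partition(partition)
    design = as_design(design, Y.shape[1])
    dataset, _ = _combat_core(Y, design, partition, empirical_bayes=eb, var_ddof=var_ddof)
    return dataset


def covbat_harmonize(
    data,
    design=None,
    partition=None,
    variance_retained: float = 0.95,
    eb: bool = True,
    score_eb: bool = False,
    var_ddof: int = 0,
) -> HarmonizedDataset:
    """ComBat followed by location/scale adjustment of leading PC scores.

    The residual covariance of the ComBat output is eigendecomposed; the
    smallest number of leading principal components whose eigenvalues reach
    ``variance_retained`` of the total variance have their scores
    re-harmonized (location/scale, no covariates), then the residuals are
    reassembled and the fitted mean re-added.
    """
    if not 0.0 <= variance_retained <= 1.0:
        raise ValueError("variance_retained must be in [0, 1]")
    Y = _values(data)
    partition = _as_partition(partition)
    design = as_design(design, Y.shape[1])
    combat_ds, combat_fit = _combat_core(Y, design, partition, empirical_bayes=eb, var_ddof=var_ddof)
    fitted_mean = combat_ds.components["intercepts"] + combat_ds.components["covariate_effects"]
    resid = combat_ds.values - fitted_mean  # V x n

    cov = np.cov(resid, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    frac = np.cumsum(np.clip(evals, 0, None)) / np.clip(evals, 0, None).sum()
    if variance_retained <= 0:
        n_pcs = 0
    else:
        n_pcs = int(np.searchsorted(frac, variance_retained) + 1)
        n_pcs = min(n_pcs, min(resid.shape))

    score_fit = None
    if n_pcs == 0:
        harmonized = combat_ds.values.copy()
    else:
        Phi = evecs[:, :n_pcs]  # V x K
        scores = Phi.T @ resid  # K x n
        # EB pools information across features; with a single retained score
        # there is nothing to pool, so fall back to the closed form.
        score_ds, score_fit = _combat_core(
            scores, CovariateDesign.empty(resid.shape[1]), partition,
            empirical_bayes=(score_eb and n_pcs >= 2), var_ddof=var_ddof,
        )
        scores_adj = score_ds.values
        resid_adj = resid - Phi @ scores + Phi @ scores_adj
        harmonized = fitted_mean + resid_adj

    components = {
        "intercepts": combat_ds.components["intercepts"],
        "covariate_effects": combat_ds.components["covariate_effects"],
        "residuals": harmonized - fitted_mean,
    }
    dataset = HarmonizedDataset(
        values=harmonized,
        components=components,
        method="covbat",
        provenance={
            "variance_retained": float(variance_retained),
            "n_pcs": int(n_pcs),
            "empirical_bayes": bool(eb),
            "score_empirical_bayes": bool(score_eb),
        },
    )
    dataset.provenance["explained_fraction"] = float(frac[n_pcs - 1]) if n_pcs else 0.0
    return dataset


class AdjResHarmonizer(BaseHarmonizer):
    """Adjusted-residuals harmonization: remove scanner-specific feature means."""

    def __init__(self):
        pass

    def _harmonize(self, values, design, partition):
        return adjres_harmonize(values, design, partition)


class ComBatHarmonizer(BaseHarmonizer):
    """Per-feature location/scale harmonization with empirical-Bayes shrinkage.

    Parameters
    ----------
    empirical_bayes : bool, default True
        Shrink per-scanner location/scale estimates across features
        (normal / inverse-gamma parametric priors). Disable for the exact
        closed-form per-feature adjustment.
    var_ddof : int, default 0
        Divisor convention of the within-scanner variance (0: population,
        single-scanner ComBat is a no-op; 1: the R/sva convention).
    """

    def __init__(self, empirical_bayes: bool = True, var_ddof: int = 0):
        self.empirical_bayes = empirical_bayes
        self.var_ddof = var_ddof

    def _harmonize(self, values, design, partition):
        dataset, fit = _combat_core(
            values, design, partition,
            empirical_bayes=self.empirical_bayes, var_ddof=self.var_ddof,
        )
        self.combat_fit_ = fit
        return dataset


class CovBatHarmonizer(BaseHarmonizer):
    """ComBat plus covariance harmonization of leading PC scores.

    Parameters
    ----------
    variance_retained : float, default 0.95
        Smallest leading-PC variance fraction whose scores are
        re-harmonized.
    empirical_bayes : bool, default True
        EB shrinkage in the feature-level ComBat stage.
    score_empirical_bayes : bool, default False
        EB shrinkage in the PC-score stage.
    """

    def __init__(
        self,
        variance_retained: float = 0.95,
        empirical_bayes: bool = True,
        score_empirical_bayes: bool = False,
        var_ddof: int = 0,
    ):
        self.variance_retained = variance_retained
        self.empirical_bayes = empirical_bayes
        self.score_empirical_bayes = score_empirical_bayes
        self.var_ddof = var_ddof

    def _harmonize(self, values, design, partition):
        return covbat_harmonize(
            values,
            design,
            partition,
            variance_retained=self.variance_retained,
            eb=self.empirical_bayes,
            score_eb=self.score_empirical_bayes,
            var_ddof=self.var_ddof,
        )
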