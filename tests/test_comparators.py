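import shutil
import subprocess

import numpy as np
import pytest

from relief_harmonize import (
    AdjResHarmonizer,
    ComBatHarmonizer,
    CovBatHarmonizer,
    CovariateDesign,
    LinkedFactorSimConfig,
    ScannerPartition,
    adjres_harmonize,
    combat_harmonize,
    covariance_frobenius_diff,
    covbat_harmonize,
    fit_covariate_model,
    relief_harmonize,
    simulate_linked_factor_design,
)

from conftest import make_dataset


class TestAdjRes:
    def test_identity_when_no_scanner_structure(self, rng, two_scanner_partition):
        """Data whose residuals have exactly zero within-scanner means pass through."""
        n = two_scanner_partition.n_subjects
        X = rng.standard_normal((n, 2))
        design = CovariateDesign(X)
        resid = rng.standard_normal((5, n))
        # project onto the joint complement of design and batch indicators so
        # the residuals have zero covariate projection AND zero scanner means
        B = np.zeros((n, 2))
        B[np.arange(n), two_scanner_partition.scanner_index] = 1.0
        D_all = np.column_stack([B, X])
        coef, *_ = np.linalg.lstsq(D_all, resid.T, rcond=None)
        resid -= (D_all @ coef).T
        Y = 1.0 + (rng.standard_normal((5, 2)) @ X.T) + resid
        out = adjres_harmonize(Y, design, two_scanner_partition)
        np.testing.assert_allclose(out.values, Y, atol=1e-8)

    def test_mean_shift_removed(self):
        """Two features, +5 shift on scanner 2, intercept-only model."""
        Y = np.array([[1.0, 2.0, 3.0, 6.0, 7.0, 8.0], [0.0, 0.0, 0.0, 5.0, 5.0, 5.0]])
        partition = ScannerPartition(np.repeat(["a", "b"], 3))
        out = adjres_harmonize(Y, None, partition)
        for v in range(2):
            m = [out.values[v, partition.indices(i)].mean() for i in range(2)]
            assert m[0] == pytest.approx(m[1], abs=1e-10)

    def test_larger_covariance_gap_than_relief(self):
        """On planted scanner-specific latent structure, mean removal alone
        leaves a larger between-scanner covariance difference."""
        ds = simulate_linked_factor_design(LinkedFactorSimConfig(individual_strength=2.0, seed=7))
        adj = adjres_harmonize(ds.data, ds.covariates, ds.partition)
        rel = relief_harmonize(ds.data, ds.covariates, ds.partition)
        d_adj = covariance_frobenius_diff(adj.values, ds.partition, ds.covariates)
        d_rel = covariance_frobenius_diff(rel.values, ds.partition, ds.covariates)
        assert d_rel < d_adj


class TestComBat:
    def test_single_scanner_no_eb_is_identity(self, rng):
        Y = rng.standard_normal((6, 20)) * 3.0 + 2.0
        partition = ScannerPartition(np.repeat("one", 20))
        X = rng.standard_normal((20, 2))
        out = combat_harmonize(Y, CovariateDesign(X), partition, eb=False)
        np.testing.assert_allclose(out.values, Y, atol=1e-9)

    def test_hand_checkable_location_scale(self):
        """Two features, intercept-only: per-scanner standardization to pooled moments."""
        Y = np.array([[0.0, 2.0, 4.0, 10.0, 20.0, 30.0], [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]])
        partition = ScannerPartition(np.repeat(["a", "b"], 3))
        out = combat_harmonize(Y, None, partition, eb=False)
        y = Y[0]
        grand = 0.5 * (y[:3].mean() + y[3:].mean())
        resid = np.concatenate([y[:3] - y[:3].mean(), y[3:] - y[3:].mean()])
        sd_pool = np.sqrt(np.mean(resid**2))
        z = (y - grand) / sd_pool
        expected = np.empty(6)
        for idx in (slice(0, 3), slice(3, 6)):
            blk = z[idx]
            expected[idx] = (blk - blk.mean()) / blk.std()
        expected = expected * sd_pool + grand
        np.testing.assert_allclose(out.values[0], expected, atol=1e-10)

    def test_no_eb_matches_closed_form_oracle(self, rng):
        """Direct per-feature location/scale formula recomputation."""
        Y, design, partition, _ = make_dataset(rng, V=8, sizes=(10, 14), scanner_shift=1.0, scale=(1.0, 2.0))
        out = combat_harmonize(Y, design, partition, eb=False)
        M, n = 2, Y.shape[1]
        B = np.zeros((n, M))
        B[np.arange(n), partition.scanner_index] = 1.0
        D = np.column_stack([B, design.values])
        bh, *_ = np.linalg.lstsq(D, Y.T, rcond=None)
        grand = (partition.sizes / n) @ bh[:M]
        stand = grand[:, None] + (design.values @ bh[M:]).T
        resid = Y - (D @ bh).T
        sd = np.sqrt((resid**2).mean(axis=1))[:, None]
        zdat = (Y - stand) / sd
        expected = np.empty_like(Y)
        for i in range(M):
            idx = partition.indices(i)
            blk = zdat[:, idx]
            expected[:, idx] = (blk - blk.mean(axis=1, keepdims=True)) / blk.std(axis=1, keepdims=True)
        expected = expected * sd + stand
        np.testing.assert_allclose(out.values, expected, atol=1e-9)

    def test_location_scale_effects_removed(self, rng):
        """Planted location/scale-only effects: harmonized per-scanner moments align."""
        Y, design, partition, _ = make_dataset(
            rng, V=100, sizes=(40, 40), q=2, scanner_shift=2.0, scale=(1.0, 2.0)
        )
        out = combat_harmonize(Y, design, partition, eb=True)
        _, _, resid = fit_covariate_model(out.values, design)
        blocks = partition.blocks(resid)
        mean_gap = np.abs(blocks[0].mean(axis=1) - blocks[1].mean(axis=1))
        var_ratio = blocks[0].var(axis=1) / blocks[1].var(axis=1)
        assert np.median(mean_gap) < 0.2
        assert 0.7 < np.median(var_ratio) < 1.4

    def test_eb_shrinks_toward_raw_estimates_with_sample_size(self, rng):
        """gamma*/phi* approach the per-scanner estimates as n_i grows."""
        gaps = []
        for ni in (10, 100, 1000):
            Y, design, partition, _ = make_dataset(
                rng, V=60, sizes=(ni, ni), q=0, scanner_shift=1.0, scale=(1.0, 1.5)
            )
            est = ComBatHarmonizer(empirical_bayes=True).fit(Y.T, batch=partition.labels)
            fit = est.combat_fit_
            gaps.append(
                np.abs(fit.gamma_star - fit.gamma_hat).max()
                + np.abs(fit.phi_star**2 - fit.delta2_hat).max()
            )
        assert gaps[2] < gaps[1] < gaps[0]

    def test_constant_feature_within_scanner_rejected(self, rng):
        Y = rng.standard_normal((4, 12))
        Y[2, :6] = 7.0
        partition = ScannerPartition(np.repeat(["a", "b"], 6))
        with pytest.raises(ValueError, match="constant"):
            combat_harmonize(Y, None, partition, eb=False)

    def test_covariates_confounded_with_batch_rejected(self, two_scanner_partition):
        ind = (two_scanner_partition.scanner_index == 1).astype(float)
        with pytest.raises(ValueError, match="confounded"):
            combat_harmonize(
                np.random.default_rng(0).standard_normal((4, 14)),
                CovariateDesign(ind[:, None], ["dup_batch"]),
                two_scanner_partition,
            )


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not on PATH")
class TestAgainstSvaCombat:
    def test_matches_bioconductor_sva(self, rng, tmp_path):
        """Cross-check the EB ComBat against sva::ComBat (var_ddof=1, the sva
        convention) on a small dataset with covariates."""
        Y, design, partition, _ = make_dataset(
            rng, V=25, sizes=(12, 18), q=2, scanner_shift=1.0, scale=(1.0, 1.6)
        )
        np.savetxt(tmp_path / "y.csv", Y, delimiter=",")
        np.savetxt(tmp_path / "x.csv", design.values, delimiter=",")
        (tmp_path / "batch.txt").write_text("\n".join(map(str, partition.labels)))
        script = f"""
        suppressMessages(library(sva))
        y <- as.matrix(read.csv('{tmp_path}/y.csv', header=FALSE))
        x <- as.matrix(read.csv('{tmp_path}/x.csv', header=FALSE))
        batch <- readLines('{tmp_path}/batch.txt')
        out <- ComBat(dat=y, batch=batch, mod=model.matrix(~x))
        write.table(out, '{tmp_path}/out.csv', sep=',', row.names=FALSE, col.names=FALSE)
        """
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        oracle = np.loadtxt(tmp_path / "out.csv", delimiter=",")
        ours = combat_harmonize(Y, design, partition, eb=True, var_ddof=1)
        np.testing.assert_allclose(ours.values, oracle, atol=5e-4)


class TestCovBat:
    def test_zero_variance_retained_equals_combat(self, rng):
        Y, design, partition, _ = make_dataset(rng, V=15, sizes=(12, 12))
        cb = combat_harmonize(Y, design, partition)
        cvb = covbat_harmonize(Y, design, partition, variance_retained=0.0)
        np.testing.assert_allclose(cvb.values, cb.values, atol=1e-10)

    def test_pc1_variance_inflation_equalized(self, rng):
        """Scanner 2 inflates variance along one direction only; after the
        PC-score pass the leading-score variances match across scanners."""
        V, n_half = 20, 250
        direction = np.zeros(V)
        direction[0] = 1.0
        Q, _ = np.linalg.qr(rng.standard_normal((V, V)))
        base = rng.standard_normal((V, 2 * n_half))
        data = Q @ base
        idx2 = slice(n_half, 2 * n_half)
        data[:, idx2] += 2.0 * np.outer(Q[:, 0], base[0, idx2])  # inflate PC1 3x
        partition = ScannerPartition(np.repeat(["a", "b"], n_half))
        out = covbat_harmonize(data, None, partition, variance_retained=0.3, eb=False)
        resid = out.values - out.values.mean(axis=1, keepdims=True)
        cov = np.cov(resid, ddof=1)
        evals, evecs = np.linalg.eigh(cov)
        pc1 = evecs[:, -1]
        scores = pc1 @ resid
        v1 = scores[:n_half].var()
        v2 = scores[n_half:].var()
        assert abs(v1 - v2) / max(v1, v2) < 0.10

    def test_reduces_covariance_gap_relative_to_combat(self):
        """PC-shift simulated data: the score pass narrows the covariance gap."""
        from relief_harmonize import PCShiftSimConfig, simulate_pc_shift_design

        ds = simulate_pc_shift_design(
            PCShiftSimConfig(n_per_scanner=(150, 150), shift_rank=5, seed=3)
        )
        cb = combat_harmonize(ds.data, None, ds.partition)
        cvb = covbat_harmonize(ds.data, None, ds.partition, variance_retained=0.95)
        gap_cb = covariance_frobenius_diff(cb.values, ds.partition)
        gap_cvb = covariance_frobenius_diff(cvb.values, ds.partition)
        assert gap_cvb < gap_cb

    def test_provenance_records_settings(self, rng):
        Y, design, partition, _ = make_dataset(rng, V=10, sizes=(10, 10))
        out = covbat_harmonize(Y, design, partition, variance_retained=0.8)
        assert out.provenance["variance_retained"] == 0.8
        assert out.provenance["n_pcs"] >= 1


class TestCovariatePreservation:
    @pytest.mark.parametrize("method", ["adjres", "combat", "covbat"])
    def test_fitted_effects_readded_unchanged(self, rng, method):
        Y, design, partition, _ = make_dataset(rng, V=15, sizes=(20, 20), scanner_shift=1.0)
        func = {"adjres": adjres_harmonize, "combat": combat_harmonize, "covbat": covbat_harmonize}[method]
        out = func(Y, design, partition)
        assert set(out.components) >= {"intercepts", "covariate_effects"}
        total = sum(out.components.values())
        np.testing.assert_allclose(out.values, total, atol=1e-9)


class TestComparatorEstimators:
    @pytest.mark.parametrize(
        "cls", [AdjResHarmonizer, ComBatHarmonizer, CovBatHarmonizer]
    )
    def test_sklearn_interface(self, rng, cls):
        Y, design, partition, _ = make_dataset(rng, V=10, sizes=(10, 12))
        est = cls()
        out = est.fit_transform(Y.T, batch=partition.labels, covariates=design)
        assert out.shape == Y.T.shape
        assert est.dataset_.method in {"adjres", "combat", "covbat"}
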