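# relief-harmonize

Multivariate harmonization of multi-scanner (multi-site, multi-batch)
feature matrices. When the same measurements — tract-level diffusion
metrics, cortical thickness, expression panels — are collected on different
scanners or in different batches, non-biological differences contaminate
the data in three distinct ways: additive per-feature offsets (*location*
effects), per-scanner noise variance (*scale* effects), and structured
low-rank variation that only one scanner exhibits (*latent* scanner
effects). Classical per-feature corrections handle the first two;
this package implements RELIEF, which additionally isolates and removes
the third by a linked low-rank factorization, together with the standard
reference methods (AdjRes, ComBat, CovBat), simulation designs for
benchmarking them, and harmonization-quality metrics.

## The model

For a features-by-subjects matrix `Y` (V × n) partitioned into scanner
blocks `Y = [Y₁; …; Y_M]` with covariates `X` (n × q):

```
Y = A + βX′ + [Γ₁; …; Γ_M] + R + [I₁; …; I_M] + [δ₁E₁; …; δ_M E_M]
```

- `A`, `βX′` — intercepts and covariate effects (preserved),
- `Γᵢ` — scanner-specific feature means (removed),
- `R` — low-rank latent variation shared by all scanners, e.g. unmodelled
  biology (preserved),
- `Iᵢ` — low-rank latent variation specific to scanner i (removed),
- `δᵢEᵢ` — unit-variance noise scaled per scanner (variance homogenized).

Fitting proceeds in four steps: (i) two-step regression removing `A + βX′`
and then `Γᵢ`; (ii) per-scanner noise scales `δ̂ᵢ` estimated from the median
singular value of each residual block against the Marčenko–Pastur median,
and block standardization `Δ = [residᵢ/δ̂ᵢ]`; (iii) the nuclear-norm-penalized
linked factorization

```
min ½‖Δ − R* − I*‖²_F + λ‖R*‖⋆ + Σᵢ λᵢ‖Iᵢ*‖⋆ ,   λ = √V + √n, λᵢ = √V + √nᵢ
```

solved by block coordinate descent with singular-value soft-thresholding;
(iv) reassembly `Ŷ = Â + β̂X′ + [δ̂ᵢR̂ᵢ*] + δ̄Ê` with
`δ̄² = Σᵢ nᵢδ̂ᵢ² / n`, so shared variation returns on its original scale
and noise variance is equalized across scanners.

Covariates you intend to *test* downstream should not be passed as
covariates during harmonization — re-adding a fitted effect whose noise
context was altered inflates false positives (the package's simulation
protocol quantifies this).

## Worked example

```python
import relief_harmonize as rh

# planted two-scanner dataset: 100 features, 50+50 subjects, 4 nuisance
# covariates, strong scanner-specific latent structure (c = 2)
ds = rh.simulate_linked_factor_design(
    rh.LinkedFactorSimConfig(individual_strength=2.0, seed=7))

est = rh.ReliefHarmonizer().fit(
    ds.data.T, batch=ds.partition.labels, covariates=ds.covariates)

print(est.noise_scales_.delta)      # [1.361 1.339]  (true draws: 1.341 1.328)
print(est.decomposition_.ranks)     # {'shared': 3, 'individual': [3, 4]}
```

The estimated noise scales recover the planted values and the factorization
finds the planted rank-3 structures. Comparing all four methods on the same
dataset with the built-in metrics (covariance homogeneity = Frobenius norm
of the between-scanner covariance difference; scanner predictability =
leave-one-out QDA, where *chance level means success*):

```
          cov_frobenius_diff  qda_accuracy  qda_auc
  raw                 67.039          0.72    0.816
  adjres              67.040          0.66    0.746
  combat              64.803          0.67    0.750
  covbat              58.953          0.51    0.524
  relief              42.909          0.43    0.423
```

RELIEF yields both the most homogeneous covariances and scanner prediction
at or below chance.

## Command line

```bash
relief-harmonize harmonize --data fa.tsv --covar covars.tsv --batch scanner \
    --method relief --out fa_harmonized.tsv --components
relief-harmonize evaluate --data raw=fa.tsv --data rel=fa_harmonized.tsv \
    --covar covars.tsv --batch scanner --out metrics.tsv
relief-harmonize simulate --config sim.yaml --out simdir
relief-harmonize evaluate-sim --config study.yaml --out results.tsv
```

Input layout: features-by-subjects delimited text (first column feature
IDs, header row subject IDs; `--transpose` for the other orientation), a
subjects-by-covariates table, and batch labels as a covariate column name
or a one-label-per-line file.

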