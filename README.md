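# mbgp — multi-breed genomic prediction

A tested pipeline for genomic prediction in multi-breed livestock
populations, built around three prediction methods and an
across-sire-family cross-validation scheme:

- **Pedigree BLUP** (model 1): `y = 1μ + Xb + Z₁a + Z₁Qq + e` with
  `a ~ N(0, σₐ²A)` and random breed regressions `q ~ N(0, σ_q²I)` on
  pedigree-derived breed fractions Q.
- **GBLUP** (model 2): adds a genomic term `g ~ N(0, σ_g²G)` with G
  built from SNP dosages (distinct diagonal/off-diagonal estimator by
  default; a cross-product variant for SNP-BLUP equivalence).
- **BayesR** (model 3): marker effects from a four-component normal
  mixture with variances (0, 10⁻⁴, 10⁻³, 10⁻²)·σ_g², Dirichlet mixing
  proportions, Gibbs sampling with a numba kernel, run on phenotypes
  pre-adjusted for fixed and breed effects.

Because no suitable public dataset ships with the package, a
first-class **synthetic data module** generates multi-breed pedigrees
(two cohorts: many ~40-progeny sire families sampled widely, plus a
few large families), drops genotypes through them with recombination
from breed-specific founder frequencies (Balding–Nichols divergence),
draws mixture-distributed marker effects, and builds phenotypes with
fixed effects, breed effects and a controlled heritability.

## Layout

| module | contents |
|---|---|
| `mbgp.simulate` | breed frequencies, pedigree, gene drop, marker effects, phenotypes, missingness injection |
| `mbgp.qc` | SNP call-rate / MAF / HWE / LD filters, animal filters, mean-dosage imputation, audit report |
| `mbgp.relationships` | pedigree A (tabular method + direct inverse), genomic G, breed composition Q, relatedness summaries |
| `mbgp.mixed_models` | design building, REML (profiled single-kernel + Nelder–Mead multi-kernel), Henderson MME solver, GBLUP prediction, phenotype adjustment |
| `mbgp.bayesr` | Gibbs sampler, multi-chain runner, posterior summaries, large-effect report, GEBV from marker effects |
| `mbgp.cross_validation` | family-atomic subset design, fold orchestration with leakage assertions, accuracy / bias / relatedness statistics by sire breed |
| `mbgp.io` | plain-text VCF, dosage matrix, pedigree/phenotype CSV, relationship matrices |

## CLI

All stages are exposed under one entry point:

```sh
mbgp simulate --config sim.yaml --out data/            # synthetic dataset
mbgp qc --genotypes data/dosages.txt --out qc/         # filters + imputation
mbgp nrm --pedigree data/pedigree.csv --out A.csv
mbgp grm --genotypes qc/genotypes_qc.txt --out G.csv --freq-min 0.005
mbgp reml --phenotypes data/phenotypes.csv --pedigree data/pedigree.csv \
          --model-config model.yaml --out vc.csv
mbgp predict ... --validation-ids holdout.txt --out preds.csv
mbgp bayesr --phenotypes ... --genotypes ... --out bayesr/
mbgp cv --phenotypes ... --pedigree ... --genotypes ... --out cv/
```

`sim.yaml` holds `SimConfig` fields (`n_snp`, `n_sires_A`,
`family_size_A`, `n_sires_B`, `family_size_B`, `h2`, `fst`,
`missing_rate`, `seed`, ...). `model.yaml` holds the model
specification:

```yaml
response: trait
fixed_factors: [sex, birth_type, rearing_type, contemporary_group]
covariates: [age, hcwt]          # drop hcwt for DRESS/LMY-style traits
random_terms:
  - {name: polygenic, kind: A}
  - {name: genomic,   kind: G}
  - {name: breed,     kind: breed}
```

## Conventions

- Contemporary group is birth year × site × slaughter group.
- QC defaults: SNP call rate ≥ 0.95, MAF ≥ 0.01, HWE p ≥ 1e-15,
  r² ≤ 0.99 within a 100-SNP window, animal call rate ≥ 0.90, mean
  heterozygosity ≤ 0.5. Stage order: SNP filters, then animal filters,
  then imputation.
- G uses pooled allele frequencies over all genotyped animals; SNPs
  with frequency < 0.005 are excluded.
- Cross-validation keeps sire families whole, holds one cohort-A
  subset (~500 animals) out per fold, and always keeps cohort B in the
  reference. Accuracy is the Pearson correlation of predictions with
  (adjusted) phenotypes divided by h from model 1; bias is the OLS
  slope of observed on predicted (1 = unbiased). Validation phenotypes
  are deleted from every fit, including the adjustment step, and a
  leakage assertion runs on every fold.
- BayesR production defaults are 10 chains × 50,000 iterations (20,000
  burn-in); tests and the CLI default to desk-scale settings
  (3 × 5,000 / 2,000).
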