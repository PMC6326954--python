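# relapsekit

Genomic relapse-risk prediction for allogeneic stem-cell-transplant cohorts,
rebuilt as a tested, reusable pipeline. The package covers the full analysis
chain:

- **`relapsekit.simulate`** — synthetic case/control cohorts with a known
  causal structure: latent-Gaussian LD blocks, planted logistic genotype and
  covariate effects, calibrated prevalence, duplicated samples with
  GQ-dependent genotyping error, injected missingness, and imputed genotype
  posteriors with per-call dosage uncertainty.
- **`relapsekit.qc`** — genotype quality control: duplicate-sample
  concordance curves over GQ hard-cutoff thresholds, GQ/DP hard filtering,
  restriction to biallelic variants, ALT allele frequencies.
- **`relapsekit.covariates`** — genetic PCA with an eigenvalue-stabilization
  rule for the component count, greedy collinearity pruning, a nominal
  univariable logistic screen against relapse, and a PC-loading locality
  report (e.g. MHC region on chr6).
- **`relapsekit.cv`** — the core engine: leave-one-out cross-validation in
  which every fold re-runs a covariate-adjusted per-variant logistic
  association filter on the training samples only, fits a random-forest
  probability classifier on the fold-selected variants, and scores the
  held-out sample. A deliberately broken variant (selection before CV) is
  exposed for leakage-contrast testing only.
- **`relapsekit.performance`** — one-sided Mann-Whitney tests, rank-based
  ROC/AUC, stratified percentile-bootstrap AUC confidence intervals, AUC
  power at a given alpha, and the odds-ratio-of-correct-prediction curve.
- **`relapsekit.importance`** — variant ranking by LOOCV-aggregated forest
  importance and by a label-permutation-calibrated full-data importance
  (Altmann scheme; the association filter is re-run inside each
  permutation), plus rule-based top-variant selection.
- **`relapsekit.replication`** — evaluation of a fixed top-variant list in
  an independent cohort: position+allele variant matching with strand-swap
  dosage flips, the missing-genotype complete-case trade-off, imputed-dosage
  SD quality filtering, and LOOCV refitting on the frozen variant set.

## Test

```sh
python -m pytest -q tests/
```

The suite includes `tests/test_acceptance.py`, which certifies the
pipeline's statistical properties end to end (null calibration of the
nested LOOCV AUC, the leakage contrast against the broken pipeline, planted
signal recovery, exact Mann-Whitney oracles, bootstrap CI coverage,
permutation-importance validity, QC-curve behaviour, replication
degradation under imputation noise, and format round-trips). The heavier
simulation-based criteria run at desk scale and take a few minutes each.

## CLI

A `relapsekit` console script mirrors the pipeline stages:

```sh
relapsekit simulate config.yaml --seed 7 --out-prefix cohort --plink
relapsekit qc cohort.vcf --gq-min 18 --duplicates pairs.tsv --out-prefix qc
relapsekit screen cohort.vcf cohort.meta.tsv --n-pcs auto
relapsekit predict cohort.vcf cohort.meta.tsv --p-threshold 0.001 \
    --n-trees 1000 --mode genetic-only --out-prefix predictions
relapsekit evaluate predictions.tsv --n-boot 2000 --out-prefix eval
relapsekit rank cohort.vcf cohort.meta.tsv --n-perm 200 --out importance.tsv
relapsekit replicate panel.vcf panel.meta.tsv importance.tsv --max-missing 1
```

`simulate` takes a YAML file of `SimConfig` fields (`n_samples`,
`n_variants`, `maf_range`, `ld_block_size`, `ld_rho`, `n_causal`,
`causal_beta`, `covariate_effects`, `prevalence_target`, `seed`, ...).
Genotypes are read/written as VCF 4.2 (GT:GQ:DP), PLINK 1.9
.bed/.bim/.fam, or tab-separated dosage tables; metadata as TSV; reports as
JSON/TSV.

## A note on nesting

The pipeline's central design point is that variant selection happens
*inside* every cross-validation fold. `relapsekit.cv.leaky_loocv_predict`
implements the classic mistake (selection once on all samples, then CV) and
exists purely so the test suite can demonstrate the optimistic bias it
produces on null data; never use it for performance estimates.
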