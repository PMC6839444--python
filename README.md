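# mircohort

Analysis toolkit for serum microRNA qPCR-array (TLDA-style) case–control
cohorts: Ct preprocessing and global-mean normalization, derived
endocrine/metabolic clinical variables, covariate-adjusted differential and
correlation statistics, and multi-miRNA ROC panels for metabolic-syndrome
detection — plus a seeded synthetic-cohort generator so every stage is
testable without external data.

## Modules

| module                | what it does |
|-----------------------|--------------|
| `mircohort.simulate`  | seeded synthetic cohorts: Ct matrices with planted group fold changes, correlated assay clusters and detectability structure; clinical tables with per-group location/scale distributions and a latent metabolic-severity factor; ground-truth records |
| `mircohort.qpcr`      | Ct table parsing (long/wide), detection filtering (absolute + relative rule), global-mean normalization, 2^−ΔΔCt relative quantification, per-assay CV, variance-decomposition reference-gene stability scoring, standard-curve quantification |
| `mircohort.clinical`  | free testosterone from the SHBG/albumin mass-action equilibrium, HOMA-IR, rule-based metabolic-syndrome classification (≥3 of 5 criteria), androgen stratification by free-T threshold (default 0.034 nmol/L, strict >) |
| `mircohort.stats`     | KS normality (+ Lilliefors option), log2 policies, per-assay t-test / ANOVA + Tukey with logistic & multinomial covariate-adjusted odds ratios, volcano tables, Fisher exact 2×2, partial Pearson correlations, correlation clustering, noncentral-t design power |
| `mircohort.panel`     | empirical ROC curves (ties count ½), DeLong AUC variance/CI and paired AUC tests, logistic marker panels (ridge fallback under separation), operating-point rules (Youden / fixed sens / fixed spec), leave-one-out panel scores |
| `mircohort.pipeline` / `mircohort.cli` | config-driven orchestration with per-stage accounting, seeded reproducibility and TSV/JSON/PNG outputs |

## CLI

```bash
mircohort validate-config config.yaml
mircohort simulate   --config config.yaml --seed 7 --out cohort/
mircohort preprocess cohort/ct_long.tsv --dialect long \
    --min-fraction 0.15 --min-samples 10 --detection-limit 35 \
    --mean-basis per_sample_detected --out pre/
mircohort clinical   cohort/clinical.tsv --out derived.tsv
mircohort run-all    --config config.yaml --seed 7 --out full_run/
```

Minimal synthetic config:

```yaml
seed: 7
output_dir: full_run
synthetic:
  n_per_group: [20, 23, 19]
  n_assays: 750
  frac_detectable: 0.4
  effects:
    - {assay: 3, fold_normo: 1.3, fold_hyper: 2.0}
  mets_effects: [[10, -1.2], [11, -1.0], [12, 1.1]]
stats:
  adjust_covariates: [age, bmi]
panel:
  outcome: mets
  within_group: pcos
```

A run emits, under `output_dir`: the derived clinical table, detection
report, ΔCt matrix, two- and three-group differential tables, volcano
coordinates + plot, partial-correlation table, panel AUC/ROC tables +
plot, panel coefficients JSON, ground truth (synthetic runs) and a
`run_report.json` with per-stage accounting. Every table header carries
the config hash and seed; identical configs reproduce byte-identical
outputs.

## Conventions worth knowing

- A well counts as *detected* when Ct is present and ≤ the detection limit
  (default 35 cycles); the detection filter keeps assays detected in at
  least `max(min_samples, ceil(min_fraction · n_samples))` samples.
- The global mean is taken per sample over that sample's detected,
  filter-passing assays by default (`common_detected` optional).
- CVs are computed on linear-scale relative quantities (configurable).
- No multiple-testing adjustment by default; Benjamini–Hochberg columns are
  available via `fdr: true`.
- Logistic odds ratios are per log2 unit of marker abundance, Wald 95% CIs;
  separation is flagged and the OR reported non-estimable rather than
  extrapolated.
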