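# itac

Integrative transcriptome + methylome analysis toolkit for a four-group
(N/E/C/T) nasal-mucosa study design:

- **datamodel / io** — validated tabular containers (expression intensities,
  β-value matrices, sample sheets, probe manifests) with a strict
  tab-separated dialect (`NA` missing values, round-trip-exact floats).
- **normalization** — per-sample LOWESS correction against the cohort median
  profile, then log2 transform and gene-median centering. Fold changes are
  computed from the unlogged (but LOWESS-corrected) intensities.
- **cluster_profiles** — restarted k-means over gene profiles under
  correlation distance (1 − Pearson), per-cluster per-group mean profiles
  with pooled-variance t-tests vs the normal group (Bonferroni m = k × 3),
  and per-gene differential tables (t, p, Bonferroni, unlogged fold change).
- **predictor** — diagnostic classifier: top discriminant genes from two
  clusters (ranked by |t| of the C/T vs N/E contrast), a mean C/T reference
  profile, per-sample Pearson correlation, and a three-way call with an
  abstention band (unpredictable for r in [−0.25, 0.25]). Evaluation reports
  sensitivity, specificity and a two-sided Fisher exact test, with
  leave-one-out support (everything — normalization, clustering, gene
  selection, reference — is rebuilt per fold).
- **methylome_ewas** — per-sample QC against a bimodal β-distribution shape,
  per-probe pooled t-tests with Bonferroni, smoothed P-values (windowed mean
  of −log10 p over genomic probe order, radius 3, per chromosome),
  methylation-state calling (β < 0.2 unmethylated, [0.2, 0.6] hemimethylated,
  > 0.6 methylated), locus-level secondary analysis, and Manhattan/volcano
  table exports.
- **replication** — cross-dataset sign concordance of differential genes.
- **synthetic_data** — seeded generators for both data types with full
  planted truth: 10 profile archetypes, named planted genes with exact
  unlogged fold changes (CDX2-analog 2.46, CACNA1C-analog 1.52), bimodal
  methylomes with two planted tumor-hemimethylated CpG islands and
  QC-failing flattened samples.

## Tests

```
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (oracle
equivalences at 1e-12, planted-partition recovery, smoothing/state
properties, QC separation, planted-locus recovery rate, and the
sensitivity/specificity/fold-change targets at reduced replicate counts).

## CLI

```
itac simulate expr --seed 1 --out data/            # synthetic expression + truth
itac simulate meth --seed 1 --out meth/            # synthetic methylomes + manifest
itac io validate --expr data/expression.tsv --sheet data/samples.tsv
itac normalize --expr data/expression.tsv --sheet data/samples.tsv --out norm/
itac cluster --norm norm/normalized_log_centered.tsv --sheet data/samples.tsv \
    --k 10 --runs 100 --seed 17 --out clusters/
itac predict --expr data/expression.tsv --sheet data/samples.tsv --loo --out pred/
itac ewas --beta meth/beta_tumor.tsv --control-beta meth/beta_control.tsv \
    --manifest meth/manifest.tsv --islands CpG:84,CpG:41 --out ewas/
itac replicate --stats-a a.tsv --stats-b b.tsv --out concordance.tsv
```

`simulate` accepts `--scenario file.yaml` with flat keys overriding the
scenario defaults (e.g. `n_genes`, `noise_sd`, `n_probes`).

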