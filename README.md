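# dscore

Signed single-sample enrichment scoring of disulfidptosis susceptibility and
the downstream pan-cancer analyses around it:

- **Scoring** — a from-scratch single-sample rank-based enrichment engine
  (integrated running-sum statistic, rank-position weights, configurable
  exponent and cohort-range normalization). The **D-score** of a sample is
  the promoter-set enrichment minus the suppressor-set enrichment over a
  curated 43-gene regulator panel (9 promoters, 34 suppressors) bundled as
  package data.
- **Screening** — a recurrence-based pan-cancer correlation screen: per
  cancer type, every gene's expression is Spearman-correlated with the
  D-score, p-values are Benjamini–Hochberg adjusted within type, and genes
  passing |rho| > 0.45 with adjusted p < 0.05 in ≥ 11 types are called
  candidate promoters/suppressors. Merging candidates into the core panel
  yields the extended panel behind the **D-score+**.
- **CRISPR validation** — preranked GSEA (max-deviation weighted KS
  statistic, gene-label permutation null, NES, two-tailed smoothed p) of
  candidate sets against a ranked normZ list.
- **Association** — hallmark-pathway correlation maps, genomic-aberration
  signature correlations with average-linkage row clustering, a PCA-based
  EMT score (PC1, marker-oriented sign), and Wilcoxon rank-sum two-group
  comparisons (exact for small untied samples).
- **Survival** — median-split Kaplan–Meier grouping, a log-rank test, and a
  Cox proportional-hazards model (Breslow ties, Newton iteration, Wald CIs).
- **Simulation** — a synthetic multi-cancer cohort generator that plants
  every structure the pipeline assumes (latent susceptibility factor,
  candidate genes calibrated to a target Spearman correlation with the
  *realized* score, cancer-type-specific survival hazards, metastasis
  shifts, signature columns of both signs, a ranked list with planted
  extremes) plus a two-arm glucose-starvation contrast. Everything is
  reproducible from a seed and ships with a truth table.

No external data are required; all analyses run on generated cohorts.

## CLI

```bash
dscore simulate --seed 1 --out-dir sim/
dscore compute  --expr sim/expression.tsv --annotations sim/annotations.tsv \
                --panel core --out scores.tsv
dscore screen   --expr sim/expression.tsv --annotations sim/annotations.tsv \
                --scores scores.tsv --out-dir screen/
dscore gsea-validate --ranked sim/ranked_normz.tsv --sets sim/planted_sets.gmt \
                --perms 1000 --seed 7
dscore signatures --signatures sim/signatures.tsv --annotations sim/annotations.tsv \
                --scores scores.tsv --out-prefix sig
dscore emt      --expr sim/expression.tsv --gmt emt.gmt --marker VIM --out emt.tsv
dscore compare  --scores scores.tsv --annotations sim/annotations.tsv --by mstage
dscore survival --scores scores.tsv --clinical sim/clinical.tsv
dscore pipeline --out-dir run/ --seed 1        # full end-to-end, writes report.json
```

`--panel` accepts `core` (bundled 43-gene panel), `plus` (core extended with
the bundled candidate table), a two-column TSV (gene, role) or a GMT with
`promoters`/`suppressors` sets.

## Notes on conventions

- Enrichment scores use rank-*position* weights, making per-sample scores
  invariant under any strictly increasing transform of that sample's
  expression; ties break by matrix gene order, deterministically.
- Cohort-range normalization (when enabled) pools the promoter and
  suppressor score range so the difference stays on one scale.
- Median splits send ties to "low" everywhere (stratifier and survival
  grouping alike).
- The bundled candidate-regulator table reproduces the published list's row
  counts and directions with placeholder symbols; see the data file header.
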