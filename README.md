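# stagespec

Stage-specific gene expression analysis for two-group time-course
transcriptomics.

Disease processes such as kainic-acid-induced epilepsy unfold in stages: an
acute progression phase in which control and case transcriptomes diverge,
followed by a remission phase in which they re-converge. `stagespec` is a
toolkit for finding the genes that mark each stage of such a time course
(control vs. case groups sampled with replicates at a handful of time points,
e.g. 1, 6, 24, 72 and 240 h) and for characterizing what those genes do. It
is aimed at bioinformaticians analyzing bulk expression matrices from designs
of this shape.

## What it computes

**Tau specificity index.** For each gene, a representative linear-scale
expression `X_i` is the mean over case replicates at stage `i` (of `N`
stages). Two indices measure how concentrated the profile is:

    tau_max = Σ_{i=1..N} (1 − X_i / X_max) / (N − 1)
    tau_min = Σ_{i=1..N} (1 − X_min / X_i) / (N − 1)

Both range from 0 (uniform expression) to 1 (expressed in, or depleted from,
exactly one stage). `tau_max` flags genes specifically *high* at one stage,
`tau_min` genes specifically *low*; a gene's overall specificity is
`tau = max(tau_max, tau_min)`, and genes with `tau ≥ 0.8` are called
stage-specific, assigned the stage of their extreme value and a direction
(up/down).

**Stage partition.** A pathway gene set (e.g. an excitability-linked
signaling pathway) is scored per sample with single-sample GSEA; the
case-sample mean score per time point forms a trajectory whose peak splits
the course into progression (time points up to and including the peak) and
remission (after it).

**Supporting machinery**, each usable on its own:

- transcriptome heterogeneity: PCA on the 500 most variable genes,
  per-time-point mean between-group Euclidean distance and Pearson
  correlation of group-mean profiles;
- single-sample GSEA (rank-weighted integral, exponent 0.25), preranked GSEA
  with a gene-set-permutation null (NES, add-one p-values), and
  hypergeometric over-representation with Benjamini–Hochberg correction;
- validation of called genes in an independent dataset with normality-gated
  two-group tests (Shapiro–Wilk → Student's t or Wilcoxon rank-sum);
- immune infiltration: ssGSEA immune score, marker-set cell-type scores,
  non-negative least-squares deconvolution against a user signature matrix,
  and gene × cell-type Spearman correlation with hierarchical clustering;
- a synthetic-data generator that plants stage-specific genes, a pathway
  trajectory, an immune signature and cell-type mixtures with known ground
  truth, so every step has a recovery test.

## Worked example

The `demo` command generates the default synthetic study — 2000 genes,
5 time points × 2 groups × 3 replicates, 10 up + 10 down stage-specific
genes planted per stage at log2 fold change 3, a 50-gene pathway peaking at
24 h, a 60-gene immune signature rising from 24 h — and runs the full
pipeline on it:

```sh
stagespec demo --seed 0 --out demo_run
```

prints

```
peak enrichment at 24 h (progression stages: [1.0, 6.0, 24.0])
stage-specific genes at tau >= 0.8: 100
validation (changed/total per stage class): {'progression': '56/60', 'remission': '35/40'}
immune score significant at (h): [6.0, 24.0, 72.0, 240.0]
stages completed: 7/7
```

Reading the output: the pathway trajectory peaks at 24 h, so 1–24 h is the
progression phase and 72–240 h the remission phase; Tau calling at 0.8
recovers exactly the 100 planted stage-specific genes; most of them
reproduce a significant control-vs-case change in the matched validation
dataset (fresh measurement noise, same planted design); and the immune score
separates the groups from the 24 h onset onward — the extra 6 h call in this
particular run is a false positive at the nominal 5% level of the per-time
test. Result tables (Tau per gene, partition, enrichment, immune scores,
correlations) and a manifest land in `demo_run/results/`.

The same workflow runs on real data from a YAML config
(`stagespec run --config cfg.yaml --out results/`), and every step is also a
library function (`stagespec.tau_index`, `stagespec.gsea_preranked`, …) and
a CLI subcommand (`stagespec tau`, `stagespec ssgsea`, `stagespec ora`,
`stagespec deconvolve`, …).

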