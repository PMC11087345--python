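# Methods

## Design being modeled

The package targets a two-group time-course design: a control and a case
(lesioned/induced) group, each measured with a few replicates at an ordered
set of time points. The default layout — 5 time points (1, 6, 24, 72, 240 h)
× 2 groups × 3 replicates, 30 arrays — is the classic rodent
status-epilepticus time course. Case time points are treated as the *stages*
of the disease trajectory; control samples anchor divergence and group
tests but are excluded from stage profiles (stage specificity is a property
of the case trajectory; a case-relative-to-control variant would be a
different statistic and is not implied by the Tau formulas).

## Tau specificity index

Per gene, the stage profile is `X_i = mean over case replicates at stage i`,
computed on the **linear** scale (log2 input is back-transformed per sample
first, so the profile is `mean(2^x)`, not `2^mean(x)`). The two indices

    tau_max = Σ (1 − X_i/X_max) / (N − 1)
    tau_min = Σ (1 − X_min/X_i) / (N − 1)

are ratios of expression levels, which is the reason for the linear-scale
requirement: ratios of log-ratios are meaningless. Numerical choices:

- profiles are floored at `ε = 1e-8` so `tau_min`'s division never hits
  zero; genes whose profile is entirely zero before flooring are excluded
  and reported rather than floored into fake uniformity. A one-stage-only
  gene's `tau_max` comes out within ~2e-9 of 1 (not exactly 1, because the
  floored stages contribute `ε/X_max`).
- a gene's overall specificity is `tau = max(tau_max, tau_min)`; the two
  indices target complementary patterns (specifically high vs. specifically
  low) and neither dominates the other, so the natural single-number summary
  is the larger. Both are always reported so either convention can be
  applied downstream.
- the assigned stage is the argmax (for `tau_max`) or argmin (for
  `tau_min`) of the profile, ties broken toward the earlier stage; the
  calling threshold `tau ≥ 0.8` is boundary-inclusive.
- calling at threshold `t` returns genes sorted by descending tau, then gene
  id — a total, reproducible order.

## Stage partition

A pathway gene set is scored per sample by ssGSEA; the trajectory is the
mean score over case samples per time point and the peak is its argmax (ties
toward the earlier time point, matching the "earliest onset" reading of a
plateau). Progression = time points ≤ peak, remission = time points > peak.
A peak at the final time point is legal but leaves the remission phase empty
and warns, since a rise-only trajectory gives no evidence of remission.

## Enrichment statistics

**ssGSEA** follows the rank-weighted integral form: per sample, expression
values receive ascending average ranks `r` (ties averaged; walk order ties
broken by gene id for bit-reproducibility), and the score is
`Σ_i [P_in(i) − P_out(i)]` walking the ranking top-down, with `P_in`
accumulating `r^α` over in-set genes (α = 0.25 by default) and `P_out`
counting out-of-set genes. The score is invariant to monotone transforms of
a sample's values; min–max normalization across samples is available but
off by default — both knobs are exposed because published analyses rarely
state them.

**Preranked GSEA** uses the classic running sum (in-set increments
`|metric|^w / Σ|metric|^w`, uniform out-of-set decrements, ES = maximum
deviation from zero; an all-zero in-set weight vector falls back to uniform
increments). The null is **gene-set permutation**: `n_perm` random same-size
sets drawn from the ranked universe (vectorized via the sorted-positions
identity that the running sum's extrema occur adjacent to set members). NES
divides ES by the mean |null ES| of same-sign permutations and
`p = (b + 1)/(m + 1)` over same-sign permutations, so p is never 0 and is
uniform under the null (verified by simulation in the acceptance checks).
With a roughly sign-symmetric null, the minimal attainable p is about
`2/n_perm`, not `1/n_perm` — worth remembering when thresholding at very
small p. If no permutation shares the observed sign, NES is flagged
undefined and p is reported at its floor `1/(n_perm + 1)`.

**Over-representation** is the one-sided hypergeometric upper tail
(`scipy.stats.hypergeom.sf`) per set intersected with the universe, BH
correction across tested sets, results sorted by p then set name. Raw p is
reported alongside BH q because stage-gene follow-up conventionally
thresholds on raw p < 0.05.

## Heterogeneity

PCA runs on the `n_top = 500` genes with the highest across-sample standard
deviation (ties by gene id), centered but **not** scaled — the genes were
selected *by* SD, so flattening SD structure would contradict the selection.
Component signs are fixed by requiring each loading vector to have a
non-negative sum. Between-group divergence per time point is the mean
Euclidean distance over all control × case sample pairs on all genes (the
unbiased aggregation when the pairing of replicates is arbitrary), and the
companion correlation is Pearson r between group-mean profiles.

## Validation and group tests

All two-group comparisons use one convention: Shapiro–Wilk at 0.05 in each
group; if both groups are compatible with normality, a pooled-variance
two-sided t-test, otherwise a two-sided Wilcoxon rank-sum (exact when sizes
permit and ties are absent). Groups of fewer than 3 samples or with constant
values cannot be normality-tested and fall through to the rank test; two
identical constant groups give p = 1. A called gene is "changed" in a
validation dataset when any per-time-point raw p < 0.05; BH-corrected calls
(across all gene × time tests) are emitted alongside for transparency, and
genes absent from the validation matrix are reported as not testable rather
than silently dropped.

Operating characteristics worth knowing: with n = 3 per group the rank-sum
test's smallest two-sided p is 0.1, so whenever the normality gate diverts a
3 vs 3 comparison to the rank branch it cannot reach 0.05 — power at 3 vs 3
is capped near the gate's pass rate (~0.90) regardless of effect size, and
a pattern that requires joint non-significance at two null time points at
α = 0.05 cannot hold in more than ~(0.95)² ≈ 90% of replicates even with
perfect power elsewhere. The acceptance checks report the measured pattern
rate at the default design rather than adjusting the design to the target.

## Immune infiltration

The immune score is the ssGSEA score of a user-supplied immune gene list.
Cell-type abundance has two modes: marker-set ssGSEA (free scores,
comparable within a type across samples) and non-negative least squares of
the linear-scale bulk profile on a user signature matrix over shared genes,
with coefficients renormalized to proportions and the per-sample residual
norm reported as the fit diagnostic. Fixed-signature tools from the
literature are deliberately not replicated — their signature matrices are
tied to specific platforms/species and are inputs here, not constants; the
permutation-based sample p-value of those tools is likewise replaced by the
residual norm. Signatures must be full column rank on the shared genes;
collinear columns are named in the error. Gene × cell-type association is
Spearman rho with a t-approximation p (exact permutation enumeration
available for n ≤ 10 samples); genes are clustered by average linkage on
`1 − corr(rho rows)` with a configurable cut (default 3 groups, mirroring a
three-stage gene grouping; no claim that 3 is right for arbitrary data).

## Synthetic data generator

The generator emulates the design above on the log2 scale: per-gene
baselines `Normal(6, 1.5)` (typical microarray log2 intensity spread), iid
`Normal(0, 0.3)` measurement noise per sample, and additive case-only
effects — so effects are multiplicative on the linear scale and
back-transformed values stay positive:

- stage-specific genes: ±3 log2 units (8-fold) at exactly one stage, a
  deliberately strong planted effect representing acutely induced genes;
  `n_specific_per_stage` counts each direction separately;
- pathway: a shared additive shift following a triangle in log-time
  (amplitude 1.5 at the peak, reaching zero 2 natural-log-hours away, so
  adjacent time points get partial activation and the trajectory is
  unimodal);
- immune signature: a rise-and-stay shift (+1.5 log2) from an onset time
  point onward;
- cell mixtures: linear-scale `signature · proportions` with log-normal
  noise, plus a well-conditioned random signature factory (disjoint
  8×-boosted marker blocks over log-normal background).

The design (which genes are planted) and the noise derive from one seed;
`noise_seed` redraws only the noise, which is how matched validation
datasets are produced. The generator does **not** simulate probe-level
artifacts, batch effects, normalization residue, gene–gene correlation
beyond the planted modules, or platform differences between discovery and
validation datasets — so passing recovery tests demonstrate correctness of
the estimators under the stated model, not robustness to real-data
preprocessing, and real validation datasets (different platforms, time
grids and species mappings) will behave less cleanly than the matched
synthetic ones.

## Pipeline

`run_pipeline` executes heterogeneity → trajectory → partition → Tau →
validation → enrichment (ORA + preranked GSEA on the peak-time case−control
log2 difference) → immune, writing every table through the io layer with a
documented sort key; stages lacking their optional inputs are marked
skipped. The manifest records version, parameters, seed and per-stage row
counts but no timestamps, so identical configs reproduce byte-identical
outputs. One master seed drives the run; the GSEA stage derives its seed by
a fixed offset so adding stages never shifts existing streams. Elapsed
times go to the log, not the manifest.

## Problem sizes in the checks

The bundled acceptance checks run at desk scale, chosen to make each
property measurable with comfortable margins: 1000 random profiles for the
Tau oracle; the full 2000-gene default study for planted recovery; 600
genes × 5 peak positions for partition recovery; 200 + 500 null runs at
1000 permutations for GSEA calibration; 50 mixtures of a 200-gene, 5-type
signature for deconvolution; 100 replicate studies of 1000 genes for the
immune pattern rate.

## I/O conventions and limitations

Matrices are delimited text with opaque string gene ids — no probe
annotation, symbol aliasing or GEO retrieval; duplicate gene rows are
collapsed by mean (a declared policy; summarization method is usually
unstated in deposited series), rows entirely missing are dropped, any other
missing cell is an error rather than an imputation. Gene sets are Broad
GMT. Plotting is intentionally out of scope; all outputs are tables meant
for downstream tooling.
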