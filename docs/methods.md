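# Methods

This note documents the models, defaults and numerical choices behind
`uvkinet`, and what the synthetic test-bed does and does not establish.

## Study design and data model

The unit of analysis is a gene × sample matrix of non-negative,
linear-scale normalized intensities with a design of
`group ∈ {control, uv}`, `week ∈ {1, 2, 4, 6, 8}`, `replicate`.
Controls exist at week 1 (the reference for all fold changes) and — when
the drift filter is used — at week 8. Loaders validate and refuse to
repair: missing values, negative intensities and design/matrix
mismatches are errors naming the offending gene or sample, because
silent imputation would corrupt downstream correlations. Gene ids are
opaque case-sensitive strings; symbol/alias resolution is a curation
task outside the method.

## DEG cascade

Order is fixed and counts are monotone along it:

1. **Low-intensity filter** (`low_intensity_q`, default 0.20). "Low"
   is defined against the pooled intensity distribution: a gene is
   dropped only if it is below the pooled `q`-quantile in *every*
   sample. The conjunctive reading keeps any gene detectably expressed
   somewhere. Detection-call ("absent") masks from array software can
   be applied upstream by subsetting the matrix; they are not modeled.
2. **Intrinsic-drift exclusion** (`drift_fold`, default 1.5). A gene is
   excluded iff `max(m8/m1, m1/m8) ≥ drift_fold` where `m_w` is the
   control mean at week *w*. This removes chronological-aging signal
   from a UV contrast that spans eight calendar weeks.
3. **Fold change and test.** `log2FC(g, w) = log2 uvmean(g, w) −
   log2 ctrlmean_w1(g)`. The per-week test is Welch's two-sample t on
   log2 intensities (standard for 3-vs-3 arrays; pooled-variance t is a
   flag away), BH-adjusted across genes *within each week*; a pooled
   adjustment across all gene-weeks is available (`pooled_fdr`). Both
   group means constant and equal gives p = 1 by convention; p is
   clipped into (0, 1].
4. **Selection.** DEG iff some week has `|log2FC| ≥ 1` and `q ≤ 0.05`
   (both thresholds are parameters). Direction is the sign at the
   *qualifying* week of largest `|log2FC|`; restricting to qualifying
   weeks keeps the direction label consistent with the selection rule
   when the globally largest excursion is not significant. An exact
   up/down magnitude tie resolves to "down" (deterministic, and
   repression dominates this biology).

## Kinetic clustering

K-means (Lloyd, Euclidean) on the raw log2FC vectors; `n_init = 50`
seeded restarts, best inertia kept; empty clusters are repaired by
re-seeding to the farthest point (scikit-learn's behavior). Profiles
are *not* standardized by default: depth of repression is part of what
distinguishes kinetic classes (a trajectory that falls 2-fold in week 1
is a different kinetic from one that falls 4-fold); `standardize=True`
gives shape-only clustering. K is user-fixed (defaults 3 up / 5 down);
no automatic K selection is attempted. Cluster identity is only
meaningful up to relabeling — comparisons should use ARI, never raw
labels — and `set_concentration` computes how strongly a gene set
piles into a union of clusters, feeding the enrichment arithmetic.

## Overrepresentation

All quantities come from the table `[[k, n−k], [K−k, N−n−K+k]]` with
memberships intersected with the background universe before counting;
a selection gene absent from the background is an error (a silent
universe mismatch would bias every fold). Folds are computed in exact
rational arithmetic and rounded only for display (2 d.p.; percentages
1 d.p.). Fisher's exact test is the hypergeometric tail ("greater") or
the point-probability two-sided sum; the chi-square default is without
Yates correction (the bundled cluster-concentration table is
significant at p < 0.001 either way, which the tests check). Plain
Fisher is implemented rather than DAVID's EASE score: EASE q-values
depend on DAVID's GO universe and version and cannot be regenerated
from membership lists, whereas the fold enrichments can — those are the
reproducible quantities, and the bundled reported q-values are carried
for display only.

## Co-expression network and prediction

The network is the Pearson correlation matrix of per-gene log2FC
trajectories (5 time points), built by default over downregulated DEGs
only — seeds and candidates are co-repressed, and this matches the
prediction pool the design implies — with the full both-direction
network available for export. A constant trajectory has no defined
correlation; it is stored as r = 0 and the gene flagged, so it can
never pass a positive threshold (a flat profile carries no
co-expression evidence). r is clipped to [−1, 1] after computation to
absorb floating-point overshoot.

Thresholding is on *signed* r (`edge iff r ≥ τ`): the grid
0.001–0.999 spans only positive values and anti-correlated genes are
not evidence of shared membership in a co-repressed module.
`absolute=True` thresholds |r| for users who want the variant.

**Nested LOOCV.** The outer loop holds out each seed; the inner loop,
on the remaining training seeds, holds out each one across the whole
τ grid and records its fractional rank (ties get the mean of the
spanned ranks — scores take only a handful of integer values, so
fractional ranks avoid the optimistic bias of "first" ranking). The
per-fold optimal τ minimizes the mean inner-loop rank, ties resolving
to the smallest τ (deterministic). An *outlier* seed — rank above 200
at every τ — is excluded from the tuning mean (`evaluation` policy,
default); `scoring` additionally removes it from the seeds that score
the test gene. The evaluation pool for a held-out seed is every network
gene except the scoring seeds, so a 514-gene network with 10 training
seeds yields the 504-gene pool. The final ranking scores all non-seed
genes with all seeds at the median per-fold optimal τ (even-length
medians snap to the nearest grid value, ties toward the smaller) and
keeps the top k with no score cutoff; emitted lists are ordered
score-descending then gene-id-ascending for byte-stable output.

**Permutation test.** Null seed sets are drawn uniformly without
replacement from all network genes. The publication-scale procedure
(10^7 replicates) cannot re-run nested tuning per replicate, and the
original null construction is not fully specified — this is the
package's largest assumption, so it is explicit: with
`tau_policy="fixed"` (default) the statistic for the observed seeds and
every null replicate alike is the median leave-one-seed-out rank at a
single τ (the nested procedure's median optimal τ), making observed
and null the same functional and large B cheap; `tau_policy="nested"`
re-runs the full nested procedure per replicate for small B. The
add-one estimator `p = (n_leq + 1)/(B + 1)` never returns 0; default
B = 10^4 in the CLI-scale configuration, 999 in the test-bed.

## Synthetic generator

`log2 intensity = baseline + effect(gene, group, week) + N(0, sd_gene)`,
intensities `2^(·)` — Normal noise on log2 (log-normal intensities) is
the standard multiplicative error model for array data; the real
study's noise model is unknown, and this is an assumption. Defaults
are the test-bed's study conditions: 450 background genes, a planted
module of 11 seeds + 50 true neighbors, 25 drift genes, 3 replicates,
baseline 8.0 log2 units, background noise sd 0.25, module noise sd
0.10, module loadings a_g ~ U(0.8, 1.2) on a shared latent kinetic
(the week-2-recovery repression archetype), drift fold 2.0. The eight
archetype templates are qualitative shape matches to the canonical
photoaging kinetics (acute/subacute/sustained induction; five
repression shapes distinguished by week-2 recovery, depth, and late
decline); their numeric values are generator defaults, not published
quantities, and are configurable. Background genes cycle through all
eight archetypes plus flat, so roughly a third of the background shares
one of the three near-collinear repression shapes (pairwise template
correlations 0.91–0.93) — deliberate, because in real data entire
kinetic clusters co-express and the prediction problem is only
non-trivial if lookalike trajectories exist. Drift genes drift
linearly in week in *both* groups, so the week-8 control mean sits
exactly `drift_fold` above week-1 and an unfiltered analysis would
mis-call them as late UV DEGs — which is precisely what the drift
filter exists to prevent. No week-0 samples are generated; week-1
control is the reference. Identical specs (including seed) produce
bit-identical output.

### What the synthetic tests do and do not show

They establish that the implementation recovers planted structure under
a known error model: the noiseless module is recovered exactly; at
module noise 0.10 the held-out seeds' median rank lands in the top
~5–10% of a ~300-gene pool in 20/20 generator seeds with permutation
p ≤ 0.006 throughout, and 37–45 of the top-50 candidates are planted
neighbors (typical 40; the remainder are background genes whose
archetype mimics the module — at the LOOCV-selected τ ≈ 0.99 a
threshold sweep shows ~45 is the ceiling at any τ, because the tuning
criterion optimizes seed rank, not neighbor purity, and τ lands right
at the typical neighbor–seed correlation). They do not establish
performance on real arrays, which add probe effects, batch structure,
heavier-tailed noise and correlated replicates that the generator
deliberately omits.

## Problem sizes and numerics

The bundled test-bed runs at ~500 genes × 21 samples with a 999-value
threshold grid and B = 999 permutations — sizes chosen so a full
pipeline run takes seconds and the whole suite minutes on one core,
while keeping every pool large relative to the 200-rank outlier rule.
Determinism throughout: one global seed hash-derives per-stage seeds;
K-means and permutation draws are seeded; ranked lists are emitted in a
total order; network TSVs store full-precision floats (`repr`) so
write/read round-trips are exact. Known limitations: no moderated
(empirical-Bayes) variance testing, no probe-level modeling, no
automatic K or τ selection outside the LOOCV procedure, and the
permutation null's fixed-τ shortcut described above.
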