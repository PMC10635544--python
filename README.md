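# uvkinet

Time-course transcriptome analysis of UV-induced skin photoaging:
kinetic differential-expression selection with an intrinsic-aging
exclusion filter, K-means kinetic clustering, gene-set
overrepresentation, and seed-gene candidate prediction over thresholded
co-expression networks with nested leave-one-out cross-validation and
permutation significance.

The package targets the study design of chronic-UV mouse experiments
(e.g. GEO accession GSE58915): three replicates per group, UV-exposed
skin profiled at weeks {1, 2, 4, 6, 8}, with non-irradiated controls at
weeks 1 and 8 so that intrinsic (chronological) aging can be separated
from UV-driven change. It is a library first — the functions below are
the interface, `examples/` holds one narrative script per capability —
with a thin `uvkinet` command-line wrapper for staged shell runs.

## The method

**DEG cascade.** Genes whose pooled intensity is in the lowest quantile
in every sample are dropped; genes whose week-8/week-1 *control* mean
ratio exceeds 1.5-fold are excluded as intrinsic drift; a gene is a DEG
iff at some week `|log2 FC| ≥ 1` (two-fold) with Benjamini–Hochberg
`q ≤ 0.05` (Welch t on log2 intensities, UV week *w* vs week-1 control).

**Kinetic clustering.** Each DEG's trajectory is its log2 fold-change
vector over the five weeks; up- and downregulated genes are clustered
separately by Lloyd's K-means (defaults k=3 up, k=5 down, 50 restarts).

**Overrepresentation.** For a selection of size *n* from a universe of
size *N* and a gene set with *K* universe members, *k* of them selected:
fold enrichment = (k/n)/(K/N), with Fisher's exact and Pearson
chi-square tests on the 2×2 table and BH adjustment across sets.

**Candidate prediction.** The Pearson correlation matrix of the
downregulated DEG trajectories is binarized at thresholds
τ ∈ {0.001, …, 0.999}; a gene's *neighborhood score* at τ is its number
of direct connections to seed genes (known collagen-regulatory genes).
The single hyperparameter τ is tuned by nested LOOCV: the outer loop
holds out each seed and measures its fractional rank by the remaining
seeds' scores; the inner loop, within each outer fold, holds out each
training seed across the whole grid and picks the τ minimizing the mean
inner rank (after excluding an outlier seed whose rank exceeds 200 at
every τ). The final list ranks all non-seed genes at the median of the
per-fold optimal τ and keeps the top k (default 50). Significance of
the observed median held-out rank is assessed against random seed sets
of the same size, `p = (#{null ≤ observed} + 1)/(B + 1)`.

A synthetic generator (`uvkinet.synthetic`) emulates the whole design —
eight kinetic archetypes, a planted co-expressed module of 11 seeds plus
true neighbors sharing one latent kinetic, intrinsic-drift genes, and
log-normal multiplicative noise — with ground-truth labels, so every
stage is testable end to end without external data.

## Worked example

```python
import uvkinet as uk

matrix, design, truth = uk.generate(uk.SyntheticSpec(n_drift=0, rng_seed=7))
deg = uk.run_deg_pipeline(matrix)
network = uk.correlation_network(deg.profiles("down"))
result = uk.nested_prediction(network, truth.seeds, k=50)
perm = uk.permutation_test(network, truth.seeds, B=999, rng_seed=1,
                           tau=result.median_tau)
```

Running `python examples/04_candidate_prediction.py` (the same code)
prints:

```
network: 311 downregulated genes, 11 seeds
median optimal threshold: 0.988
observed median LOOCV rank of held-out seeds: 17.5 among 301 genes
top-50 candidates: 44/50 are planted true neighbors
permutation test (B=999): p = 0.001
```

The held-out seeds rank in the top ~6% of the pool (17.5 of 301), far
from the ~150 expected under no association; 44 of the 50 candidates
are planted module members (most of the rest are background genes whose
kinetic archetype closely mimics the module's); and no random 11-gene
seed set among 999 matched the seeds' coherence, so p hits the add-one
floor. `examples/03_enrichment_arithmetic.py` reproduces the published
enrichment arithmetic from the bundled gene lists — fold enrichments
2.42, 4.74, 3.02 and 3.67 with Fisher p-values matching the published
0.001 / 0.018 / 0.007 — and `examples/05_full_pipeline.py` runs the
staged pipeline (also available as `uvkinet run --config run.yaml`)
into a hashed, resumable run directory.

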