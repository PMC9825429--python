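# Methods

This note documents the models and procedures coexkit implements, the
defaults it ships, and the choices made where the design was genuinely
open.

## Coexpression construction

**Preprocessing.** RNAseq count matrices are filtered in this order:
sequencing runs (columns) with a total count below 2,000,000 are removed
(strict `<`), then genes (rows) with a mean count below 30 (strict `<`),
then every count is transformed as `log2(v + 0.125)`. The pseudo-count
0.125 = 2⁻³ maps a zero count to exactly −3. The order matters: gene
means change after run removal. Both thresholds are parameters
(`min_total`, `min_avg`); they are calibrated to sequencing-run depth at
genome scale, so on small matrices (a few hundred genes) `min_total`
should be scaled down or disabled — the run filter acts on column sums of
whatever matrix it is given.

**PC pseudo-samples.** The log2 matrix is row-centered (each gene's mean
subtracted; no variance scaling — "row-centered" is read literally) and
decomposed by SVD over the sample axis. The gene scores `U·S` of the top
1000 components (or all available, if fewer) become the new
pseudo-samples. The scores keep the singular-value weighting: the leading
components carry more variance, so Pearson correlations over the
pseudo-samples reflect the original variance structure. Whitening would
make all components equipotent, which would defeat selecting the "top"
components in the first place. Component signs are fixed so the
largest-magnitude score in each component is positive; correlation
magnitudes are sign-invariant, so this is purely for reproducible output.

**Subagged Mutual Rank.** Per iteration, `n_subsample = 50` pseudo-sample
columns are drawn without replacement from the pool (up to
`pool_size = 1000`), the gene × gene Pearson correlation matrix is
computed, converted to Mutual Rank, logit-transformed, and the
`n_iter = 1000` iterations are averaged element-wise. One seeded
generator is consumed sequentially across iterations, so the result is a
pure function of the seed.

- *Mutual Rank*: for each gene, partners are ranked by descending
  correlation (rank 1 = strongest, self excluded, ties receive average
  ranks); `MR(a,b) = sqrt(rank_a(b) · rank_b(a))`. MR is invariant under
  any strictly monotone transform of the correlations.
- *Logit transform*: MR is mapped into (0, 1) by
  `p = (MR − 0.5)/(G − 1)`, an affine map symmetric about the attainable
  rank midpoint that keeps p strictly interior for all MR in [1, G−1];
  the value is `ln((1 − p)/p)`, so MR = 1 gives the largest value. The
  natural-log base is immaterial downstream: a base change is an affine
  rescale absorbed by z-standardization (asserted in tests). The exact
  parameterization is isolated in one function (`logit_of_mr`) so an
  alternative mapping can be substituted without touching the pipeline.
- *Averaging on the logit scale*: iterations are averaged after the
  logit, not on raw MR. Averaging a bounded, roughly symmetric quantity
  is better behaved than averaging the heavily right-skewed MR itself.

**z-standardization.** The averaged matrix is standardized to mean 0,
sd 1 over all defined unordered off-diagonal pairs, with the sample
standard deviation (ddof = 1). Missing pairs stay missing. This makes
platforms and versions directly comparable.

## Integration

**Subset integration.** When a compendium is partitioned into n subsets
(n = 7 at production scale), gene filtering makes each subset's gene set
differ. Genes present in ≥ 4 of 7 subsets are retained — by pigeonhole,
any two such genes co-occur in at least one subset, so every retained
pair has a value. Per pair, the z-scores of the m covering subsets are
combined as

    (m/n)^k · (1/m) · Σ zᵢ ,   k = 0.2

a mean pulled toward zero when coverage is poor. The penalized mean is
the released value; no re-standardization is applied after subset
integration (a flag enables it).

**Union-type coexpression.** The RNAseq and microarray platforms of a
species are combined per pair: the mean where both define the pair, and
`2^(−k)·z` (the n = 2, m = 1 shrinkage) where only the complete platform
does. The result is re-standardized — the union is the *z-score of the
average*. The asymmetry with subset integration (re-standardize vs not)
is deliberate.

## Evaluation

**Pathway-consistency score.** Gene-set annotations are first propagated
up the term DAG (each term inherits all descendants' genes), then only
informative terms — strictly fewer than 50 genes — are kept; larger terms
are too generic to discriminate. The evaluation universe is the genes
with at least one informative term. Pairs sharing a term are positives,
pairs of genes from the same orthogroup are excluded outright (neither
positive nor negative; exclusion beats positivity), everything else is
negative. Pairs are ranked by descending coexpression and the ROC is
integrated by trapezoids over FPR ∈ [0, 0.01], interpolating vertically
at the ceiling; tied scores are traversed as one diagonal segment. The
area is scaled by 10,000, so 0.5 is the random expectation
(10000 · 0.01²/2) and 100 the maximum. The score depends only on the
ranking, so it is invariant under strictly increasing transforms of the
coexpression values. Labeled pairs with missing coexpression are dropped
(with a logged count), not imputed.

**Cross-platform similarity.** Orthogroups with exactly one gene in
every compared species give aligned gene lists; each platform's z-scores
over the n(n−1)/2 aligned gene pairs form a vector, and platform
similarity is the Pearson correlation of those vectors (optionally
displayed as 10-fold rounded integers). Platforms are clustered by
average linkage (UPGMA) on distance 1 − similarity.

**Confusion metrics.** The helper computes accuracy, sensitivity,
specificity and precision from raw counts; ratios with zero denominators
are reported as missing, never as 0.

## Network and map views

- *Ranked list*: partners of a guide gene in descending z, ties broken
  by gene id; z < 3 is flagged "weak" — z-scores from random profiles are
  close to standard normal, so 3 is a practical co-regulation threshold.
- *Genome network*: the union over genes of each gene's top-3 edges
  (ties at the cut broken by partner id). The union is asymmetric, so
  hub genes can exceed degree 3.
- *Guide subnetwork*: breadth-first expansion from the guide; within a
  BFS layer, candidates are admitted in descending order of their
  strongest edge into the already-admitted set (tie-break by id) until
  20 genes are collected. The expansion rule beyond "20 genes directly
  or indirectly coexpressed" is an artifact decision; BFS with
  weight-ordered admission is deterministic and favors strong local
  structure.
- *CoexMap*: UMAP (n_neighbors = 10, fixed seed, random init) on the
  precomputed dissimilarity `d = z_max − z`. Conceptually the distance
  is the negated z-score; the affine shift by the matrix maximum makes
  the values nonnegative, as metric-style embedders require, without
  changing any pair ordering (asserted in tests). Points beyond the
  0.99 radial quantile are pulled onto that radius. The map center and
  quantile radius are computed once and recorded in the embedding's
  parameters, so re-applying the displacement is an exact no-op —
  clamping about a recomputed centroid would drift, because moving
  outliers shifts the centroid.

## Synthetic data

The generator is a shared-factor Gaussian model per module on the log2
scale: with within-module correlation ρ, a member gene's log2 expression
is `μ + σ·(√ρ·f + √(1−ρ)·ε)` with one latent factor f per sample, so any
two members correlate at exactly ρ in expectation — a closed form that
the tests check by simulation. Counts are the rounded base-2 exponential
(log-normal), matching the pipeline's log2 assumption. Defaults: 5
modules × 40 genes + 100 background genes, 60 samples, ρ = 0.85, σ = 1,
μ = 8 (≈ 256 counts, a moderately expressed transcript). Annotation
terms are per-module gene subsets capped below 50 genes so they survive
informative-term selection; orthogroups pair a chosen fraction of genes
to exercise the exclusion rule; the null coexpression generator draws
i.i.d. standard normals per pair and standardizes them exactly.

What the generator does **not** emulate: count over-dispersion beyond
log-normality, batch effects, library-size variation, correlated noise
across modules, and annotation bias toward highly expressed genes.
Passing tests therefore demonstrate correctness of the machinery and
recovery under clean modular signal, not performance on real archives.

## Problem sizes and numerical choices

The test suite runs the full pipeline at desk scale: the recovery check
uses the 300-gene, 60-sample default compendium with 200 subagging
iterations of 20 pseudo-samples; the null-calibration check averages 100
seeds of a 150-gene universe; `scripts/acceptance.py` averages 100 seeds
of a 1000-gene universe (≈ 500k pairs per seed). Tolerances: z-score
standardization is exact to 1e-9; orthogonality of PC scores to 1e-8
relative; oracle equivalences (Mutual Rank, AUROC, top-k networks) to
1e-12. Degenerate inputs fail loudly: all-filtered matrices, zero
variance in standardization, fewer than 2 samples for PCA, incomplete
matrices for CoexMap. A gene with zero variance over a subsample gets
correlation 0 with all partners rather than NaN, keeping every iteration
well defined.

## Known limitations

- The logit parameterization of MR and the averaging scale are isolated
  assumptions (see above); alternative readings plug into one function.
- Subset integration at production scale (7 × ~30k genes) is dense
  in-memory; the implementation targets desk-scale matrices.
- UMAP coordinates are only guaranteed bit-stable for a fixed seed on a
  fixed platform/library version.
- Batch correction is a pass-through hook; any real correction (e.g.
  Combat) must be supplied as a callable or applied upstream.
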