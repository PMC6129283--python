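# Methods

## Model and assumptions

The ontology score rests on one assumption: for well-behaved data,
similarity between samples in expression space should increase with the
similarity of their cell-type annotations in a subclass ontology. The
score quantifies, per sample, how well that holds.

**Expected similarity (O).** Only `is_a` (subclass) edges are traversed;
`part_of` and other relations are ignored, so the ancestor set $A(t)$ is
the reflexive transitive closure over subclasses. Jaccard and cosine
similarities are computed from set sizes: for the cosine, the indicator
vectors over the full term axis contain zeros everywhere outside the two
ancestor sets, so the ontology size cancels and
$|A_i \cap A_j| / \sqrt{|A_i|\,|A_j|}$ is exact — the set-based code is
checked against a literal indicator-vector implementation in the tests.
Term-pair values are computed once per unordered pair and broadcast to
sample pairs, making O exactly symmetric. Obsolete terms are excluded by
default and mapping a sample to one is an error rather than a silent
drop, so curation mistakes surface. Terms from other namespaces reachable
via `is_a` in the loaded file are included in ancestor sets; similarity
across disconnected components is 0 under Jaccard, which is allowed.

**Observed similarity (D).** Samples are embedded by PCA of the
gene-centered matrix after $\log_2(x+1)$; the log transform is on by
default because a handful of high-expression genes otherwise dominate
PC1 on TPM-scale data (a flag reproduces raw-scale PCA). Four components
are retained by default; with so few coordinates Spearman correlation
between score vectors is coarse (few distinct rank configurations), which
is documented rather than hidden — Pearson is available as an alternative.
PCA is computed by singular value decomposition with a deterministic sign
convention (largest-magnitude gene loading positive per component), so D
is bit-reproducible across runs and platforms; this matters because
Spearman rank patterns are not invariant under per-component sign flips.

**Score (u).** $u_k$ correlates column $k$ of D with column $k$ of O over
pairwise-complete entries, with average ranks for ties (O contains many
ties by construction). The self-pair is included by default — a literal
reading of the column correlation — with a flag to drop it, since (1, 1)
is an uninformative tied maximum; on more than ~20 samples the two modes
differ by O(1/n). A score over fewer than 3 pairs, or against a constant
column (e.g. all samples share one term and the self pair is dropped), is
NA, reported with a count, and excluded from summaries.

## Reference models

The randomized-ontology null draws each sample's term uniformly **with
replacement** from all non-obsolete terms (a flag restricts the pool to
observed terms, a harder null). Replicate $i$ uses seed $\mathrm{seed}+i$,
so replicate subsets are independently reproducible, and D is computed
once per experiment — only O and u are rebuilt per replicate. The fixed
reference assigns 1.0 within a group and 0.25 otherwise. Distributions are
compared with a two-sided Wilcoxon–Mann–Whitney test: exact null
distribution for tie-free groups of ≤ 25, normal approximation with tie
correction otherwise, and p = 1 with a warning when every value ties.
Per-sample scores are pooled across replicates for the contrast.

## Noise injection

An artificial batch effect adds i.i.d. $N(\mu, \sigma^2)$ draws to every
gene value of a selected sample subset. The subset size is
round-half-away-from-zero of fraction × n, drawn without replacement;
selection is stratified per group by default so every group contains both
batches. Noise is injected on the scale the scoring consumes — after the
log transform when log preprocessing is on — because a +10 shift on raw
TPM would be negligible for highly expressed genes and overwhelming for
silent ones; a flag injects on the raw scale instead, and neither mode is
asserted to be canonical. Perturbed values are not clipped, so negatives
can occur and flow through scoring (the log transform is already done at
that point).

The intensity sweep plateaus once the injected shift fully separates the
two batches in PC space: beyond that point ($\mu \gtrsim 10$ at these
conditions) additional intensity cannot change the rank structure that
Spearman correlation sees, so the median score is constant.

## Batch adjustment

**Control genes.** $pc_g = 1 - \mathrm{rank}(\sigma_g)/\max \mathrm{rank}$
with ascending average ranks. The rank direction follows the stated goal
of preferring stable genes as controls: the smallest-sd gene gets the
highest probability, the largest-sd gene exactly 0, and under full ties
every gene gets 0 (average rank equals the maximum).

**Baseline adjuster.** Per gene, each batch is standardized by its own
mean and sd and rescaled to the grand mean and the *pooled within-batch*
sd. Using the pooled within-batch sd (not the overall sd, which includes
between-batch mean variance) makes the transform exactly idempotent and
preserves the per-gene pooled mean. With `preserve_groups` (default on,
when group labels exist) batch moments are estimated on group-centered
residuals, so biological group differences survive. Zero-sd batches are
recentered only. Known limitation: second-moment matching necessarily
redistributes injected *scatter* — when the contaminating noise sd rivals
the biological within-group sd, equalizing variances inflates clean
samples and only part of the score drop is recoverable (~43% under
N(10, 1) at these conditions). Under an additive shift (noise sd small
relative to biology) the baseline recovers the original score almost
exactly, which is the regime the adjuster-recovery checks use
(μ = 10, σ = 0.1). Full empirical-Bayes ComBat, SVA and RUV are external
methods by design; the registry binds them in by name under a
roster-preserving contract, and the oracle adjuster (subtract the exact
injected noise) bounds attainable recovery in simulations.

## Synthetic data

The generator is the package's ground truth: group mean profiles start
i.i.d. N(0, 1) at the root of a complete branching tree and accumulate
N(0, τ²) increments per edge (Brownian drift), samples scatter N(0, ε²)
around their leaf's mean, and the matrix is shifted globally to be
non-negative (a shift, not truncation, keeps the drift covariance exact).
Brownian drift is the simplest model under which ontology path distance
and expected expression distance are monotonically related — precisely
the assumption the score tests — and the tests verify that relationship
empirically over 20 seeds. Defaults (depth-3 binary tree, 8 groups × 15
samples, 500 genes, τ = 1, ε = 0.1) define the reference conditions used
by the acceptance script and the heavier tests; sweeps there use 10 noise
seeds and the randomization null 100 replicates.

What the generator does **not** emulate: count noise (negative binomial),
library-size and gene-length effects, dropout, correlated gene modules,
or annotation errors. Passing tests therefore show the machinery is
correct and the score behaves as designed when its core assumption holds
— not that any particular real dataset satisfies that assumption.

## Numerical choices

* Average ranks for all ties (Spearman, control-gene ranks, rank-sum test).
* Diagonals forced exactly: 1 in O and D (except NA for constant PC
  vectors), 0 in distance matrices.
* Alignment of D and O is explicit; a sample-order mismatch raises rather
  than silently reordering.
* TSV output uses 10-significant-digit floats; identical configuration
  and seed give byte-identical files.
* All randomness flows through `numpy.random.default_rng` seeds;
  replicate streams derive as seed + index.

## Known limitations

Scores are only meaningful for *relative* comparisons (before vs after
adjustment, method vs method); there is no absolute threshold for a
"good" score. Four PCs may under-represent datasets with many distinct
groups, and the quality of the score is bounded by the quality of the
manual sample-to-term mapping — a wrong annotation lowers the score just
as a batch effect does.
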