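# ontoscore

Ontology-based scoring of sample similarity in bulk and single-cell
transcriptomics — a quantitative way to ask whether batch-effect adjustment
helped or hurt a heterogeneous expression dataset.

## The problem

When expression data from several consortia, studies or platforms are
combined, samples often cluster by data source rather than by biology.
Batch-effect adjustment (BEA) methods try to remove that technical
variation, but judging whether an adjustment *worked* is usually done by
eyeballing PCA plots — subjective, and blind to whether biological
structure was destroyed along the way. When the samples are heterogeneous
(many tissues or cell types, little overlap between sources), a principled
yardstick is missing.

`ontoscore` provides one. Cell-type annotations drawn from a hierarchical
ontology (e.g. the Cell Ontology) encode how similar any two sample types
are *expected* to be. Comparing that expectation with the similarity
structure actually observed in the expression data yields a per-sample
score that drops when batch effects distort the data and recovers when an
adjustment restores biological structure.

## The score

For ontology terms $t_i, t_j$, let $A(t)$ be the ancestor set of $t$
(the term plus everything reachable over `is_a` edges). Term similarity is

$$\mathrm{sim}_{jac}(t_i,t_j) = \frac{|A(t_i)\cap A(t_j)|}{|A(t_i)\cup A(t_j)|},\qquad
\mathrm{sim}_{cos}(t_i,t_j) = \frac{|A(t_i)\cap A(t_j)|}{\sqrt{|A(t_i)|\,|A(t_j)|}},$$

the cosine form being the normalised inner product of the ancestor-set
indicator vectors. Broadcasting term similarities through the
sample-to-term mapping gives the **expected** similarity matrix $O$.
The **observed** matrix $D$ comes from the data: samples are embedded by
PCA (first 4 PCs by default, after $\log_2(x+1)$), and $D_{kl}$ is the
Spearman correlation of the two samples' PC coordinate vectors. The
ontology score of sample $k$ is

$$u_k = \mathrm{cor}\big(D[,k],\, O[,k]\big)$$

(Spearman by default). $u_k \approx 1$ means sample $k$ sits among
exactly the neighbours its annotation predicts; scores near 0 mean the
expression neighbourhood is unrelated to the annotation. Because the score
is per-sample it can be summarised per tissue, per batch, or per
tissue-within-batch.

Around the score, the package provides the experiment designs needed to
use it responsibly:

* **Randomized and fixed ontology nulls** (`ontoscore.nulls`) — rescore
  the same $D$ against uniformly random term assignments (the
  no-information floor) and against a two-valued 1.0/0.25 same/other-group
  matrix (group identity without graded structure).
* **Noise injection** (`ontoscore.perturbation`) — add $N(\mu,\sigma^2)$
  noise to a fraction of samples as a controlled artificial batch effect;
  sweep the fraction or the intensity.
* **Batch adjustment** (`ontoscore.bea`) — control-gene probabilities from
  per-gene sd ranks, a baseline two-moment location-scale adjuster, and a
  registry to plug in external adjusters (ComBat, SVA, RUV ports) for
  assessment; an oracle adjuster bounds what is recoverable.
* **Synthetic data** (`ontoscore.synth`) — toy ontologies plus a
  Brownian-drift expression generator whose group distances provably track
  ontology distances, so the whole pipeline is testable without downloads.

## Worked example

```python
from ontoscore import (SyntheticSpec, make_toy_ontology, simulate_expression,
                       compute_scores, randomization_experiment)

graph = make_toy_ontology(depth=3, branching=2)       # 15 terms, 8 leaf types
expr, mapping = simulate_expression(graph, SyntheticSpec(seed=0))

run = compute_scores(expr, graph, mapping)
print(run.score_series.median())                      # 0.937

res = randomization_experiment(expr, graph, mapping, n_reps=100, seed=0)
print(res.true_scores.mean(),                          # 0.937
      res.fixed_scores.mean(),                         # 0.543
      res.randomized_mean)                             # 0.020
```

The true annotations score 0.937; collapsing the ontology to a same/other
two-valued matrix costs 0.4 of score, and random annotations score ~0 —
the graded between-type structure of the ontology is real signal. The
`examples/` directory walks through each capability (scoring, nulls, noise
sweeps, adjustment assessment) with printed output; the `ontoscore` CLI
(`score`, `randomize`, `noise-sweep`, `adjust`, `simulate`) exposes the
same workflows on TSV/OBO files with deterministic, diffable output.

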