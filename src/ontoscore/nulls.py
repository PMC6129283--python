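"""Reference models for the ontology score: randomized and fixed ontologies.

Two nulls calibrate how much signal the real ontology carries:

* the *randomized-ontology* null reassigns every sample a term drawn
  uniformly from the ontology's non-obsolete terms (independently, with
  replacement) and rescores; repeated over many replicate mappings it
  yields the score distribution expected when annotations are uninformative;
* the *fixed* ontology replaces graded term similarities by a two-valued
  matrix: 1.0 for samples sharing a group label, a constant (default 0.25)
  otherwise — retaining group identity but no between-group structure.

The observed matrix D is computed once; replicates only rebuild O and u.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ontology import OntologyGraph
from .pipeline import ScoreConfig, observed_from_expression, score_against_ontology
from .scoring import RankSumResult, compare_score_groups


def randomize_mapping(
    graph: OntologyGraph,
    mapping: pd.DataFrame,
    seed: int,
    restrict_to_observed: bool = False,
) -> pd.DataFrame:
    """Replace each sample's term by a uniform random ontology term.

    Draws are independent with replacement. Group/batch labels are kept.
    With ``restrict_to_observed`` the pool is the set of terms actually
    used in ``mapping`` (a harder null); by default it is every
    non-obsolete term of the ontology.
    """
    if restrict_to_observed:
        pool = sorted(set(mapping["term_id"]))
    else:
        pool = sorted(graph.active_terms)
    if len(pool) < 2:
        raise ValueError("need >= 2 candidate terms to randomize a mapping")
    rng = np.random.default_rng(seed)
    out = mapping.copy()
    out["term_id"] = rng.choice(pool, size=len(out), replace=True)
    return out


def fixed_similarity_matrix(
    mapping: pd.DataFrame, same: float = 1.0, other: float = 0.25
) -> pd.DataFrame:
    """Two-valued expected similarity: ``same`` within a group, ``other`` across.

    Requires a ``group`` label for every sample; diagonal is 1.
    """
    if not 0.0 <= other <= same <= 1.0:
        raise ValueError(f"need 0 <= other <= same <= 1, got {other}, {same}")
    if "group" not in mapping.columns or mapping["group"].isna().any():
        raise ValueError("fixed similarity matrix requires a group label per sample")
    groups = mapping["group"].to_numpy()
    values = np.where(groups[:, None] == groups[None, :], same, other).astype(float)
    np.fill_diagonal(values, 1.0)
    samples = list(mapping["sample_id"])
    return pd.DataFrame(values, index=samples, columns=samples)


@dataclass(frozen=True)
class RandomizationExperiment:
    """Scores under the true, randomized and fixed ontologies."""

    true_scores: pd.Series
    fixed_scores: pd.Series
    randomized_scores: pd.DataFrame  # columns: replicate, sample_id, score
    replicates: pd.DataFrame  # per-replicate summary
    comparisons: pd.DataFrame  # contrast, statistic, pvalue, method

    @property
    def randomized_mean(self) -> float:
        return float(self.randomized_scores["score"].mean())


def randomization_experiment(
    expr: pd.DataFrame,
    graph: OntologyGraph,
    mapping: pd.DataFrame,
    n_reps: int = 100,
    seed: int = 0,
    config: ScoreConfig | None = None,
    fixed_same: float = 1.0,
    fixed_other: float = 0.25,
    restrict_to_observed: bool = False,
) -> RandomizationExperiment:
    """Score the true mapping against randomized and fixed references.

    Replicate ``i`` uses seed ``seed + i``, so any subset of replicates is
    reproducible on its own. Rank-sum contrasts compare the true scores
    with the pooled randomized scores and with the fixed-ontology scores.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    config = config or ScoreConfig()
    mapping = mapping.reset_index(drop=True)
    _, D = observed_from_expression(expr, config)

    true_u, _ = score_against_ontology(D, graph, mapping, config)
    fixed_o = fixed_similarity_matrix(mapping, fixed_same, fixed_other)
    from .scoring import align, ontology_score  # local to avoid cycle at import

    d_f, o_f = align(D, fixed_o)
    fixed_u = ontology_score(
        d_f, o_f, cor=config.score_cor, include_self=config.include_self
    )

    rep_rows = []
    rand_rows = []
    for i in range(n_reps):
        rmap = randomize_mapping(
            graph, mapping, seed=seed + i, restrict_to_observed=restrict_to_observed
        )
        u_i, _ = score_against_ontology(D, graph, rmap, config)
        s = u_i["score"]
        rep_rows.append(
            {
                "replicate": i,
                "mean": s.mean(),
                "median": s.median(),
                "sd": s.std(),
                "n_na": int(s.isna().sum()),
            }
        )
        rand_rows.append(
            pd.DataFrame(
                {"replicate": i, "sample_id": s.index, "score": s.to_numpy()}
            )
        )
    randomized = pd.concat(rand_rows, ignore_index=True)

    contrasts = {
        "original_vs_randomized": compare_score_groups(
            true_u["score"], randomized["score"]
        ),
        "original_vs_fixed": compare_score_groups(true_u["score"], fixed_u["score"]),
    }
    comparisons = pd.DataFrame(
        [
            {"contrast": name, "statistic": r.statistic, "pvalue": r.pvalue, "method": r.method}
            for name, r in contrasts.items()
        ]
    )
    return RandomizationExperiment(
        true_scores=true_u["score"],
        fixed_scores=fixed_u["score"],
        randomized_scores=randomized,
        replicates=pd.DataFrame(rep_rows),
        comparisons=comparisons,
    )
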