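"""End-to-end scoring pipeline: expression + ontology -> per-sample scores.

Ties together preprocessing, PCA embedding, the observed similarity matrix
D, the expected similarity matrix O, and the per-sample score u. All knobs
live in :class:`ScoreConfig` so that experiments (nulls, noise sweeps,
adjustment loops) can rerun the identical pipeline while swapping one
ingredient.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .expression import observed_similarity_matrix, pca_embed, preprocess, PCEmbedding
from .ontology import OntologyGraph, expected_similarity_matrix, validate_mapping
from .scoring import align, ontology_score


@dataclass(frozen=True)
class ScoreConfig:
    """Configuration of the scoring pipeline.

    Defaults follow the reference scheme: cosine term similarity for O,
    Spearman correlation both for D and for the score u, the first four
    principal components, and log2(x + 1) preprocessing with gene centering.
    """

    term_measure: str = "cosine"
    d_cor: str = "spearman"
    score_cor: str = "spearman"
    n_pcs: int = 4
    log_transform: bool = True
    pseudocount: float = 1.0
    center: bool = True
    include_self: bool = True

    def without_log(self) -> "ScoreConfig":
        return replace(self, log_transform=False)


@dataclass(frozen=True)
class ScoreRun:
    """Result bundle of one pipeline run."""

    scores: pd.DataFrame  # sample_id-indexed: score, n_pairs_used, term_id, ...
    D: pd.DataFrame
    O: pd.DataFrame
    embedding: PCEmbedding
    config: ScoreConfig

    @property
    def score_series(self) -> pd.Series:
        return self.scores["score"]


def _ordered_mapping(expr: pd.DataFrame, mapping: pd.DataFrame) -> pd.DataFrame:
    """Reorder mapping rows to expression column order; all samples must map."""
    m = mapping.set_index("sample_id", drop=False)
    missing = [s for s in expr.columns if s not in m.index]
    if missing:
        raise ValueError(f"samples without a term mapping: {missing[:5]}")
    return m.loc[list(expr.columns)].reset_index(drop=True)


def observed_from_expression(expr: pd.DataFrame, config: ScoreConfig) -> tuple[PCEmbedding, pd.DataFrame]:
    """Preprocess, embed and correlate: expression matrix -> (embedding, D)."""
    base = preprocess(expr, config.log_transform, config.pseudocount)
    emb = pca_embed(base, n_pcs=config.n_pcs, center=config.center)
    return emb, observed_similarity_matrix(emb, cor=config.d_cor)


def score_against_ontology(
    D: pd.DataFrame,
    graph: OntologyGraph,
    mapping: pd.DataFrame,
    config: ScoreConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score a precomputed D against an ontology mapping; returns (scores, O).

    Used by the randomization null, which recomputes O per replicate while D
    stays fixed.
    """
    O = expected_similarity_matrix(graph, mapping, measure=config.term_measure)
    d_aligned, o_aligned = align(D, O)
    u = ontology_score(
        d_aligned, o_aligned, cor=config.score_cor, include_self=config.include_self
    )
    return u, O


def compute_scores(
    expr: pd.DataFrame,
    graph: OntologyGraph,
    mapping: pd.DataFrame,
    config: ScoreConfig | None = None,
) -> ScoreRun:
    """Run the full pipeline and return scores annotated with sample labels."""
    config = config or ScoreConfig()
    mapping = _ordered_mapping(expr, mapping)
    validate_mapping(graph, mapping)
    emb, D = observed_from_expression(expr, config)
    u, O = score_against_ontology(D, graph, mapping, config)
    annotated = u.join(
        mapping.set_index("sample_id")[
            [c for c in ("term_id", "group", "batch") if c in mapping.columns]
        ]
    )
    return ScoreRun(scores=annotated, D=D, O=O, embedding=emb, config=config)
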