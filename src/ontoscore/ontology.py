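"""Subclass ontologies and ancestor-set term similarity.

A sample annotated with a cell-type (or tissue) term inherits an *expected*
similarity to every other annotated sample: the similarity between the two
terms in the ontology. Term similarity is computed from ancestor sets over
``is_a`` (subclass) edges only. For a term ``t``, the ancestor set ``A(t)``
is the reflexive transitive closure of ``t`` under ``is_a``, i.e. ``t``
itself plus everything reachable by walking towards the root(s).

Two measures are supported, both in ``[0, 1]``:

* Jaccard:  ``|A(ti) ∩ A(tj)| / |A(ti) ∪ A(tj)|``
* cosine:   ``|A(ti) ∩ A(tj)| / sqrt(|A(ti)| · |A(tj)|)``

The cosine form is the inner product of the 0/1 indicator vectors of the
two ancestor sets over the full term axis, divided by the product of their
Euclidean norms; entries outside either ancestor set contribute nothing,
so the total number of terms in the ontology cancels out and set sizes
suffice.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable

import networkx as nx
import numpy as np
import obonet
import pandas as pd

MEASURES = ("jaccard", "cosine")

#: Required / recognised columns of a sample-to-term mapping table.
MAPPING_COLUMNS = ("sample_id", "term_id", "group", "batch")


@dataclass(frozen=True)
class OntologyGraph:
    """A directed acyclic graph of ontology terms over subclass edges.

    Edges in ``dag`` point child -> direct superclass, so walking *forward*
    along edges moves towards the root. Obsolete terms may be present (when
    loaded with ``keep_obsolete=True``) but carry no outgoing ``is_a`` edges
    and are rejected by the similarity functions.
    """

    dag: nx.DiGraph
    names: dict = field(default_factory=dict)
    obsolete: frozenset = frozenset()
    _ancestor_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.dag):
            member = nx.find_cycle(self.dag)[0][0]
            raise ValueError(
                f"is_a graph is cyclic: cycle passes through term {member!r}"
            )
        stray = set(self.obsolete) - set(self.dag)
        if stray:
            raise ValueError(f"obsolete ids not in term set: {sorted(stray)[:5]}")
        for t in self.obsolete:
            if self.dag.out_degree(t):
                raise ValueError(f"obsolete term {t!r} retains is_a edges")

    @property
    def terms(self) -> frozenset:
        return frozenset(self.dag)

    @property
    def active_terms(self) -> frozenset:
        """Terms usable in similarity computations (non-obsolete)."""
        return frozenset(self.dag) - self.obsolete

    def __contains__(self, term: str) -> bool:
        return term in self.dag

    def __len__(self) -> int:
        return self.dag.number_of_nodes()

    def parents(self, term: str) -> frozenset:
        """Direct superclasses of ``term``."""
        if term not in self.dag:
            raise KeyError(f"unknown term {term!r}")
        return frozenset(self.dag.successors(term))

    def ancestors(self, term: str) -> frozenset:
        """Reflexive transitive ``is_a`` closure ``A(term)`` (contains ``term``)."""
        if term not in self.dag:
            raise KeyError(f"unknown term {term!r}")
        cached = self._ancestor_cache.get(term)
        if cached is None:
            cached = frozenset(nx.descendants(self.dag, term)) | {term}
            self._ancestor_cache[term] = cached
        return cached

    def leaves(self) -> list:
        """Terms without subclasses, sorted by id."""
        return sorted(t for t in self.dag if self.dag.in_degree(t) == 0)


def parse_obo(path, keep_obsolete: bool = False) -> OntologyGraph:
    """Load an OBO flat file, keeping only ``is_a`` edges.

    Parameters
    ----------
    path : str or file-like
        OBO v1.2/1.4 file with ``[Term]`` stanzas.
    keep_obsolete : bool
        If True, obsolete terms are retained in the term set (flagged in
        ``OntologyGraph.obsolete``, without is_a edges). By default they are
        excluded entirely, so mapping a sample to one fails loudly.

    Raises
    ------
    ValueError
        If the ``is_a`` graph contains a cycle.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # obonet warns on missing headers
        multi = obonet.read_obo(path, ignore_obsolete=False)
    obsolete = {
        n
        for n, d in multi.nodes(data=True)
        if str(d.get("is_obsolete", "")).lower() == "true"
    }
    dag = nx.DiGraph()
    names: dict = {}
    for n, d in multi.nodes(data=True):
        if n in obsolete and not keep_obsolete:
            continue
        dag.add_node(n)
        names[n] = d.get("name", n)
    for child, parent, rel in multi.edges(keys=True):
        if rel != "is_a":
            continue
        if child in obsolete:  # invariant: obsolete terms keep no is_a edges
            continue
        if child in dag and parent in dag:
            dag.add_edge(child, parent)
    kept = obsolete if keep_obsolete else set()
    return OntologyGraph(dag=dag, names=names, obsolete=frozenset(kept))


def _check_scorable(graph: OntologyGraph, term: str) -> None:
    if term not in graph:
        raise KeyError(f"unknown term {term!r}")
    if term in graph.obsolete:
        raise KeyError(f"term {term!r} is obsolete and cannot be scored")


def term_similarity(
    graph: OntologyGraph, t_i: str, t_j: str, measure: str = "cosine"
) -> float:
    """Pairwise ancestor-set similarity of two terms, in ``[0, 1]``.

    Symmetric in its term arguments; equals 1 iff the ancestor sets are
    identical (in particular when ``t_i == t_j``).
    """
    if measure not in MEASURES:
        raise ValueError(f"measure must be one of {MEASURES}, got {measure!r}")
    _check_scorable(graph, t_i)
    _check_scorable(graph, t_j)
    a = graph.ancestors(t_i)
    b = graph.ancestors(t_j)
    inter = len(a & b)
    if measure == "jaccard":
        return inter / len(a | b)
    return inter / math.sqrt(len(a) * len(b))


def validate_mapping(graph: OntologyGraph, mapping: pd.DataFrame) -> None:
    """Validate a sample-to-term mapping table against an ontology.

    ``mapping`` must have columns ``sample_id`` and ``term_id`` (``group``
    and ``batch`` optional), unique sample ids, and every term present and
    non-obsolete in ``graph``.
    """
    for col in ("sample_id", "term_id"):
        if col not in mapping.columns:
            raise ValueError(f"mapping is missing required column {col!r}")
    dup = mapping["sample_id"][mapping["sample_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate sample ids in mapping: {sorted(set(dup))[:5]}")
    terms = set(mapping["term_id"])
    unknown = sorted(t for t in terms if t not in graph)
    if unknown:
        raise ValueError(f"mapping references unknown terms: {unknown[:5]}")
    dead = sorted(t for t in terms if t in graph.obsolete)
    if dead:
        raise ValueError(f"mapping references obsolete terms: {dead[:5]}")


def expected_similarity_matrix(
    graph: OntologyGraph, mapping: pd.DataFrame, measure: str = "cosine"
) -> pd.DataFrame:
    """Sample-level expected similarity matrix O.

    Each entry is the term similarity of the two samples' annotated terms;
    term-pair values are computed once per unordered pair and broadcast to
    every sample pair sharing that pair, which guarantees exact symmetry.
    The diagonal is exactly 1.
    """
    validate_mapping(graph, mapping)
    samples = list(mapping["sample_id"])
    terms = list(mapping["term_id"])
    uniq = sorted(set(terms))
    tsim = pd.DataFrame(1.0, index=uniq, columns=uniq)
    for ti, tj in combinations(uniq, 2):
        s = term_similarity(graph, ti, tj, measure)
        tsim.loc[ti, tj] = s
        tsim.loc[tj, ti] = s
    values = tsim.loc[terms, terms].to_numpy(dtype=float)
    np.fill_diagonal(values, 1.0)
    return pd.DataFrame(values, index=samples, columns=samples)


def similarity_to_distance(sim: pd.DataFrame) -> pd.DataFrame:
    """Convert a similarity matrix in [0, 1] to distances ``1 - sim``."""
    values = np.asarray(sim, dtype=float)
    if np.nanmin(values) < -1e-12 or np.nanmax(values) > 1 + 1e-12:
        raise ValueError("similarities must lie in [0, 1]")
    dist = 1.0 - sim
    if dist.shape[0] == dist.shape[1]:
        np.fill_diagonal(dist.values, 0.0)
    return dist
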