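"""Shared fixtures: tiny hand-built ontologies and synthetic datasets."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from ontoscore import (
    OntologyGraph,
    ScoreConfig,
    SyntheticSpec,
    make_toy_ontology,
    simulate_expression,
)


def graph_from_edges(edges, extra_terms=(), obsolete=()) -> OntologyGraph:
    """Build an OntologyGraph from (child, parent) pairs."""
    dag = nx.DiGraph()
    dag.add_edges_from(edges)
    dag.add_nodes_from(extra_terms)
    return OntologyGraph(dag=dag, obsolete=frozenset(obsolete))


def random_dag(n_terms: int, seed: int, max_parents: int = 3) -> OntologyGraph:
    """Random DAG: node i may attach to parents among nodes < i."""
    rng = np.random.default_rng(seed)
    dag = nx.DiGraph()
    terms = [f"T:{i:03d}" for i in range(n_terms)]
    dag.add_nodes_from(terms)
    for i in range(1, n_terms):
        k = int(rng.integers(0, min(max_parents, i) + 1))
        for p in rng.choice(i, size=k, replace=False):
            dag.add_edge(terms[i], terms[int(p)])
    return OntologyGraph(dag=dag)


def brute_force_similarity(graph: OntologyGraph, t_i: str, t_j: str, measure: str) -> float:
    """Literal indicator-vector implementation over the full term axis.

    Materialises 0/1 vectors of length |terms| and evaluates the defining
    formulas directly; the independent oracle for the set-based code.
    """
    terms = sorted(graph.terms)
    vi = np.array([t in graph.ancestors(t_i) for t in terms], dtype=float)
    vj = np.array([t in graph.ancestors(t_j) for t in terms], dtype=float)
    if measure == "cosine":
        return float(vi @ vj / (np.linalg.norm(vi) * np.linalg.norm(vj)))
    inter = float(np.sum((vi == 1) & (vj == 1)))
    union = float(np.sum((vi == 1) | (vj == 1)))
    return inter / union


@pytest.fixture
def chain_graph():
    """c is_a b is_a a."""
    return graph_from_edges([("c", "b"), ("b", "a")])


@pytest.fixture
def diamond_graph():
    """d is_a b, d is_a c, b is_a a, c is_a a."""
    return graph_from_edges([("d", "b"), ("d", "c"), ("b", "a"), ("c", "a")])


@pytest.fixture
def sibling_graph():
    """a and b are siblings under root r."""
    return graph_from_edges([("a", "r"), ("b", "r")])


@pytest.fixture(scope="session")
def small_dataset():
    """Depth-2 binary tree, 4 groups x 8 samples, 200 genes: fast pipeline runs."""
    graph = make_toy_ontology(2, 2)
    spec = SyntheticSpec(depth=2, branching=2, samples_per_group=8, n_genes=200, seed=7)
    expr, mapping = simulate_expression(graph, spec)
    return graph, expr, mapping


@pytest.fixture(scope="session")
def default_dataset():
    """The reference study conditions: depth-3 binary tree, 8 x 15, 500 genes."""
    graph = make_toy_ontology(3, 2)
    expr, mapping = simulate_expression(graph, SyntheticSpec())
    return graph, expr, mapping


@pytest.fixture(scope="session")
def default_config():
    return ScoreConfig()


MINIMAL_OBO = """format-version: 1.2

[Term]
id: A:1
name: root

[Term]
id: A:2
name: child
is_a: A:1 ! root
"""

OBSOLETE_OBO = MINIMAL_OBO + """
[Term]
id: A:3
name: retired
is_obsolete: true
"""

CYCLIC_OBO = """format-version: 1.2

[Term]
id: A:1
name: one
is_a: A:2

[Term]
id: A:2
name: two
is_a: A:1
"""
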