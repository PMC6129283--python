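"""Synthetic ontologies and expression data with ontology-consistent structure.

The generator builds a complete rooted tree of terms and lets group mean
expression profiles drift down it as a Brownian walk: each child's mean is
its parent's mean plus independent ``N(0, tau^2)`` increments per gene.
Samples scatter around their leaf's mean with ``N(0, epsilon^2)`` noise.
Under this model the expected expression distance between two groups grows
with their path distance in the tree, which is exactly the assumption the
ontology score is designed to detect — so the generator provides ground
truth for every pipeline stage without any external download.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .ontology import OntologyGraph


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic dataset.

    ``tau`` is the per-edge drift sd of group mean profiles (between-group
    separation), ``epsilon`` the within-group sample sd. Defaults give a
    depth-3 binary tree (8 leaf groups), 15 samples per group and 500
    genes — a desk-scale stand-in for a multi-tissue expression compendium.
    """

    depth: int = 3
    branching: int = 2
    n_groups: int | None = None  # default: all leaves
    samples_per_group: int = 15
    n_genes: int = 500
    tau: float = 1.0
    epsilon: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1 or self.branching < 2:
            raise ValueError("need depth >= 1 and branching >= 2")
        if self.tau <= 0 or self.epsilon <= 0:
            raise ValueError("tau and epsilon must be > 0")
        if self.samples_per_group < 1 or self.n_genes < 1:
            raise ValueError("need >= 1 sample per group and >= 1 gene")


def _term_id(i: int) -> str:
    return f"TOY:{i:07d}"


def make_toy_ontology(depth: int, branching: int) -> OntologyGraph:
    """Complete ``branching``-ary tree of terms of the given depth.

    Term ids are assigned breadth-first starting from the root
    (``TOY:0000001``), so the layout is deterministic. Leaf ancestor sets
    have size ``depth + 1``.
    """
    if depth < 1 or branching < 2:
        raise ValueError("need depth >= 1 and branching >= 2")
    dag = nx.DiGraph()
    names = {}
    counter = 1
    root = _term_id(counter)
    dag.add_node(root)
    names[root] = "toy root"
    frontier = [root]
    for level in range(1, depth + 1):
        nxt = []
        for parent in frontier:
            for _ in range(branching):
                counter += 1
                child = _term_id(counter)
                dag.add_node(child)
                dag.add_edge(child, parent)  # edge child -> is_a parent
                names[child] = f"toy term level {level} #{counter}"
                nxt.append(child)
        frontier = nxt
    return OntologyGraph(dag=dag, names=names)


def simulate_expression(
    graph: OntologyGraph, spec: SyntheticSpec
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Brownian-drift expression matrix and its sample-to-term mapping.

    Mean profiles start i.i.d. standard normal at the root and accumulate
    ``N(0, tau^2)`` increments along every edge down the tree; each sample
    is its leaf's mean plus ``N(0, epsilon^2)``. The whole matrix is
    shifted by a constant to be non-negative (a global shift keeps the
    drift covariance exact). The mapping assigns each sample its leaf term,
    with the leaf as group label.
    """
    leaves = graph.leaves()
    n_groups = spec.n_groups if spec.n_groups is not None else len(leaves)
    if n_groups > len(leaves):
        raise ValueError(
            f"spec requests {n_groups} groups but the ontology has "
            f"{len(leaves)} leaves"
        )
    rng = np.random.default_rng(spec.seed)

    roots = [t for t in graph.dag if graph.dag.out_degree(t) == 0]
    if len(roots) != 1:
        raise ValueError("synthetic generator expects a single-rooted ontology")
    root = roots[0]

    means = {root: rng.normal(0.0, 1.0, size=spec.n_genes)}
    order = [root]
    while order:
        parent = order.pop(0)
        for child in sorted(graph.dag.predecessors(parent)):
            means[child] = means[parent] + rng.normal(
                0.0, spec.tau, size=spec.n_genes
            )
            order.append(child)

    groups = leaves[:n_groups]
    sample_ids = []
    columns = []
    terms = []
    for gi, leaf in enumerate(groups):
        for j in range(spec.samples_per_group):
            sample_ids.append(f"S{gi:02d}_{j:02d}")
            terms.append(leaf)
            columns.append(
                means[leaf] + rng.normal(0.0, spec.epsilon, size=spec.n_genes)
            )
    x = np.column_stack(columns)
    low = x.min()
    if low < 0:
        x = x - low

    genes = [f"G{i:04d}" for i in range(spec.n_genes)]
    expr = pd.DataFrame(x, index=genes, columns=sample_ids)
    mapping = pd.DataFrame(
        {"sample_id": sample_ids, "term_id": terms, "group": terms}
    )
    return expr, mapping


def end_to_end_benchmark(
    spec: SyntheticSpec | None = None,
    n_reps: int = 100,
    fractions=(0.0, 0.1, 0.2, 0.3, 0.4, 0.5),
    mus=(0.0, 10.0, 20.0, 30.0),
    noise_mu: float = 10.0,
    noise_sigma: float = 1.0,
    adjusters=("location_scale",),
    seed: int = 0,
    config=None,
) -> dict:
    """Run the three experiment designs on one synthetic dataset.

    Produces (1) true-vs-randomized-vs-fixed ontology comparison, (2) the
    contamination-fraction and noise-mean sweeps, and (3) per-adjuster
    before/noisy/adjusted score tables. Returns a dict of data frames (and
    the randomization experiment object under ``"randomization"``).
    """
    from .nulls import randomization_experiment
    from .perturbation import (
        NoiseSpec,
        add_gaussian_noise,
        adjust_and_rescore,
        noise_fraction_sweep,
        noise_intensity_sweep,
        _prepare_base,
    )
    from .pipeline import ScoreConfig

    spec = spec or SyntheticSpec()
    config = config or ScoreConfig()
    graph = make_toy_ontology(spec.depth, spec.branching)
    expr, mapping = simulate_expression(graph, spec)

    rand = randomization_experiment(
        expr, graph, mapping, n_reps=n_reps, seed=seed, config=config
    )
    frac = noise_fraction_sweep(
        expr, graph, mapping, fractions=fractions, mu=noise_mu, sigma=noise_sigma,
        seed=seed, config=config,
    )
    inten = noise_intensity_sweep(
        expr, graph, mapping, mus=mus, sigma=noise_sigma, seed=seed, config=config,
    )

    base, cfg = _prepare_base(expr, config, noise_on_log_scale=True)
    groups = mapping.set_index("sample_id")["group"]
    noisy, labels = add_gaussian_noise(
        base, NoiseSpec(fraction=0.5, mu=noise_mu, sigma=noise_sigma, seed=seed),
        groups=groups,
    )
    adjustment = []
    for name in adjusters:
        table = adjust_and_rescore(
            noisy, labels, graph, mapping, adjuster=name, config=cfg,
            expr_original=base,
        )
        table.insert(0, "adjuster", name)
        adjustment.append(table)

    return {
        "randomization": rand,
        "randomization_comparisons": rand.comparisons,
        "fraction_sweep": frac,
        "intensity_sweep": inten,
        "adjustment": pd.concat(adjustment, ignore_index=True),
    }
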