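"""How much signal does the ontology carry? True vs randomized vs fixed.

Rescore the same expression data (D is computed once) against three
expected-similarity models: the true annotations, 100 mappings with
uniformly random terms, and a two-valued matrix (1.0 within a group, 0.25
across). A Wilcoxon-Mann-Whitney test compares score distributions.
"""

from ontoscore import (
    SyntheticSpec,
    make_toy_ontology,
    randomization_experiment,
    simulate_expression,
)

graph = make_toy_ontology(depth=3, branching=2)
expr, mapping = simulate_expression(graph, SyntheticSpec(seed=0))

res = randomization_experiment(expr, graph, mapping, n_reps=100, seed=0)

print(f"mean score, true ontology:        {res.true_scores.mean():.3f}")
print(f"mean score, fixed 1.0/0.25 model: {res.fixed_scores.mean():.3f}")
print(f"mean score, randomized terms:     {res.randomized_mean:.3f}")
print()
print(res.comparisons.to_string(index=False))
print()
print("The true ontology scores highest: graded between-type similarity is")
print("real signal, not an artifact of group labels. Random annotations score")
print("near zero — the score collapses when annotations are uninformative.")
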