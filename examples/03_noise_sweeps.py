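"""Sensitivity of the score to an injected batch effect.

Adds Gaussian noise N(mu, 1) to a fraction of samples (stratified per
group, so every group contains clean and noisy samples) and tracks the
median score: first sweeping the contaminated fraction at mu = 10, then
sweeping mu at 50% contamination.
"""

from ontoscore import (
    SyntheticSpec,
    make_toy_ontology,
    noise_fraction_sweep,
    noise_intensity_sweep,
    simulate_expression,
)

graph = make_toy_ontology(depth=3, branching=2)
expr, mapping = simulate_expression(graph, SyntheticSpec(seed=0))

frac = noise_fraction_sweep(
    expr, graph, mapping, fractions=(0.0, 0.1, 0.2, 0.3, 0.4, 0.5),
    mu=10.0, sigma=1.0, seed=0, n_seeds=3,
)
print("median score vs contaminated fraction (mu = 10):")
print(frac[["fraction", "median"]].to_string(index=False))

inten = noise_intensity_sweep(
    expr, graph, mapping, mus=(0.0, 5.0, 10.0, 20.0, 30.0),
    sigma=1.0, fraction=0.5, seed=0, n_seeds=3,
)
print("\nmedian score vs noise mean (50% of samples contaminated):")
print(inten[["mu", "median"]].to_string(index=False))

print()
print("The score drops as more samples are contaminated, and drops with the")
print("noise mean until the batches are fully separated in PC space — beyond")
print("that (mu > 10) extra intensity cannot change the rank structure, so")
print("the score plateaus.")
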