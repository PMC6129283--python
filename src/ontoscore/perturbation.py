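"""Artificial batch effects: Gaussian noise injection, sweeps, and the
adjust-and-rescore loop.

A simulated batch effect adds independent Gaussian draws ``N(mu, sigma^2)``
to every gene value of a chosen fraction of samples; the perturbed samples
form one batch ("noisy"), the rest the other ("clean"). Sweeping the
contaminated fraction or the noise mean maps out how the ontology score
responds to increasing distortion, and the adjust-and-rescore loop measures
how much of the induced score drop a batch adjuster can recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .bea import BatchDesign, apply_adjuster
from .ontology import OntologyGraph
from .pipeline import ScoreConfig, compute_scores
from .expression import preprocess


@dataclass(frozen=True)
class NoiseSpec:
    """Parameters of one noise injection.

    ``fraction`` of samples receive independent ``N(mu, sigma^2)`` draws on
    every gene. With ``stratify_by_group`` the fraction is applied within
    each group, so every group contains both batches.
    """

    fraction: float = 0.5
    mu: float = 10.0
    sigma: float = 1.0
    seed: int = 0
    stratify_by_group: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError(f"fraction must be in [0, 1], got {self.fraction}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5))  # x >= 0 here


def add_gaussian_noise(
    expr: pd.DataFrame,
    spec: NoiseSpec,
    groups: pd.Series | None = None,
    return_noise: bool = False,
):
    """Add Gaussian noise to a fraction of samples; label the two batches.

    The number of noisy samples is ``round(fraction * n)`` (half away from
    zero), drawn without replacement — per group when stratified, over all
    samples otherwise. Clean samples are bit-identical to the input; noisy
    values are not clipped, so negatives can occur with negative ``mu``.

    Returns ``(noisy_expr, batch_labels)`` and, with ``return_noise``, the
    injected noise matrix (zeros on clean samples) as a third element.
    """
    samples = list(expr.columns)
    rng = np.random.default_rng(spec.seed)
    if spec.stratify_by_group:
        if groups is None:
            raise ValueError("stratified noise selection needs group labels")
        g = groups.loc[samples]
        chosen: list[str] = []
        for level in sorted(g.unique()):
            members = [s for s in samples if g[s] == level]
            k = _round_half_away(spec.fraction * len(members))
            chosen.extend(rng.choice(members, size=k, replace=False))
    else:
        k = _round_half_away(spec.fraction * len(samples))
        chosen = list(rng.choice(samples, size=k, replace=False))
    noisy_set = set(chosen)
    noisy_cols = [s for s in samples if s in noisy_set]  # stable column order

    noise = pd.DataFrame(0.0, index=expr.index, columns=samples)
    if noisy_cols:
        noise[noisy_cols] = rng.normal(
            spec.mu, spec.sigma, size=(expr.shape[0], len(noisy_cols))
        )
    out = expr + noise
    labels = pd.Series(
        ["noisy" if s in noisy_set else "clean" for s in samples],
        index=samples,
        name="batch",
    )
    if return_noise:
        return out, labels, noise
    return out, labels


def _prepare_base(
    expr: pd.DataFrame, config: ScoreConfig, noise_on_log_scale: bool
) -> tuple[pd.DataFrame, ScoreConfig]:
    """Return the matrix noise is injected into and the config to score it.

    By default noise is added on the same scale the scoring consumes (after
    the log transform, if enabled); ``noise_on_log_scale=False`` injects on
    the raw scale before preprocessing instead.
    """
    if noise_on_log_scale and config.log_transform:
        return preprocess(expr, True, config.pseudocount), config.without_log()
    return expr, config


def _noisy_scores(
    expr: pd.DataFrame,
    graph: OntologyGraph,
    mapping: pd.DataFrame,
    spec: NoiseSpec,
    config: ScoreConfig,
    noise_on_log_scale: bool = True,
) -> pd.DataFrame:
    base, cfg = _prepare_base(expr, config, noise_on_log_scale)
    groups = mapping.set_index("sample_id")["group"] if "group" in mapping.columns else None
    noisy, labels = add_gaussian_noise(base, spec, groups=groups)
    run = compute_scores(noisy, graph, mapping, cfg)
    out = run.scores.copy()
    out["batch"] = labels.loc[out.index]
    return out


_SUMMARY = {
    "n": "size",
    "mean": "mean",
    "median": "median",
}


def _summarize(scores: pd.DataFrame, axis: str) -> pd.DataFrame:
    def agg(s: pd.Series) -> pd.Series:
        d = s.dropna()
        return pd.Series(
            {
                "n": len(s),
                "mean": d.mean(),
                "median": d.median(),
                "q25": d.quantile(0.25),
                "q75": d.quantile(0.75),
            }
        )

    out = scores.groupby(axis, sort=True)["score"].apply(agg).unstack().reset_index()
    out["n"] = out["n"].astype(int)
    return out


def noise_fraction_scores(
    expr: pd.DataFrame,
    graph: OntologyGraph,
    mapping: pd.DataFrame,
    fractions=(0.0, 0.1, 0.2, 0.3, 0.4, 0.5),
    mu: float = 10.0,
    sigma: float = 1.0,
    seed: int = 0,
    n_seeds: int = 1,
    config: ScoreConfig | None = None,
    noise_on_log_scale: bool = True,
) -> pd.DataFrame:
    """Per-sample scores across a sweep of contaminated fractions.

    Replicate ``j`` of each fraction uses seed ``seed + j``. Returns a tidy
    frame with columns ``fraction, seed, sample_id, batch, score``.
    """
    config = config or ScoreConfig()
    rows = []
    for frac in fractions:
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"fractions must lie in [0, 1], got {frac}")
        for j in range(n_seeds):
            spec = NoiseSpec(fraction=frac, mu=mu, sigma=sigma, seed=seed + j)
            s = _noisy_scores(expr, graph, mapping, spec, config, noise_on_log_scale)
            rows.append(
                pd.DataFrame(
                    {
                        "fraction": frac,
                        "seed": seed + j,
                        "sample_id": s.index,
                        "batch": s["batch"].to_numpy(),
                        "score": s["score"].to_numpy(),
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def noise_fraction_sweep(*args, **kwargs) -> pd.DataFrame:
    """Summary table (n, mean, median, quartiles) per contaminated fraction."""
    return _summarize(noise_fraction_scores(*args, **kwargs), "fraction")


def noise_intensity_scores(
    expr: pd.DataFrame,
    graph: OntologyGraph,
    mapping: pd.DataFrame,
    mus=(0.0, 10.0, 20.0, 30.0),
    sigma: float = 1.0,
    fraction: float = 0.5,
    seed: int = 0,
    n_seeds: int = 1,
    config: ScoreConfig | None = None,
    noise_on_log_scale: bool = True,
) -> pd.DataFrame:
    """Per-sample scores across a sweep of noise means at a fixed fraction."""
    config = config or ScoreConfig()
    rows = []
    for mu in mus:
        for j in range(n_seeds):
            spec = NoiseSpec(fraction=fraction, mu=mu, sigma=sigma, seed=seed + j)
            s = _noisy_scores(expr, graph, mapping, spec, config, noise_on_log_scale)
            rows.append(
                pd.DataFrame(
                    {
                        "mu": mu,
                        "seed": seed + j,
                        "sample_id": s.index,
                        "batch": s["batch"].to_numpy(),
                        "score": s["score"].to_numpy(),
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def noise_intensity_sweep(*args, **kwargs) -> pd.DataFrame:
    """Summary table per noise mean."""
    return _summarize(noise_intensity_scores(*args, **kwargs), "mu")


def adjust_and_rescore(
    expr_noisy: pd.DataFrame,
    batch: pd.Series,
    graph: OntologyGraph,
    mapping: pd.DataFrame,
    adjuster="location_scale",
    config: ScoreConfig | None = None,
    expr_original: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Score a perturbed matrix before and after batch adjustment.

    Returns a tidy frame with columns ``sample_id, dataset, score, batch``
    where ``dataset`` is ``noisy``, ``adjusted`` and, when the unperturbed
    matrix is supplied, ``original``. All matrices are scored with the same
    configuration; ``expr_noisy`` (and ``expr_original``) must already be
    on the scale the configuration expects.
    """
    config = config or ScoreConfig()
    design = BatchDesign.from_mapping(mapping, batch=batch)
    adjusted = apply_adjuster(adjuster, expr_noisy, design)

    frames = {}
    if expr_original is not None:
        frames["original"] = compute_scores(expr_original, graph, mapping, config)
    frames["noisy"] = compute_scores(expr_noisy, graph, mapping, config)
    frames["adjusted"] = compute_scores(adjusted, graph, mapping, config)

    rows = []
    for name, run in frames.items():
        s = run.scores
        rows.append(
            pd.DataFrame(
                {
                    "sample_id": s.index,
                    "dataset": name,
                    "score": s["score"].to_numpy(),
                    "batch": batch.loc[s.index].to_numpy(),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def recovery_fraction(rescored: pd.DataFrame) -> float:
    """Share of the median score drop recovered by adjustment.

    ``(median_adjusted - median_noisy) / (median_original - median_noisy)``;
    1 means the adjuster restored the original median score exactly,
    0 means no improvement over the perturbed data. Requires all three
    datasets in ``rescored``.
    """
    med = rescored.groupby("dataset")["score"].median()
    for need in ("original", "noisy", "adjusted"):
        if need not in med.index:
            raise ValueError(f"rescored table lacks dataset {need!r}")
    drop = med["original"] - med["noisy"]
    if drop <= 0:
        raise ValueError("no score drop to recover (original <= noisy median)")
    return float((med["adjusted"] - med["noisy"]) / drop)
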