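"""Batch-effect adjustment: control-gene probabilities, a baseline adjuster,
and a registry for pluggable external adjusters.

The baseline adjuster implements the common two-moment strategy: transform
every gene so that each batch has the same mean and variance. Full
empirical-Bayes (ComBat-style), surrogate-variable and factor-removal
methods are deliberately not reimplemented here; external implementations
can be bound through the registry and assessed with the same score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats


def control_gene_probabilities(expr: pd.DataFrame) -> pd.DataFrame:
    """Per-gene control probabilities from standard-deviation ranks.

    ``pc_g = 1 - rank(sd_g) / max(rank(sd_g))`` with ascending average
    ranks: the most stable gene (smallest sd) gets pc close to 1, the most
    variable gene gets exactly 0, and when all sds tie every pc is 0
    (average rank equals the maximum rank). Control genes are those
    expected to vary little across samples.

    Returns a frame indexed by gene id with columns ``sd``, ``rank``, ``pc``.
    """
    if expr.shape[1] < 2:
        raise ValueError("need >= 2 samples to estimate per-gene sd")
    sd = expr.std(axis=1, ddof=1)
    rank = stats.rankdata(sd.to_numpy(), method="average")
    pc = 1.0 - rank / rank.max()
    return pd.DataFrame({"sd": sd, "rank": rank, "pc": pc}, index=expr.index)


@dataclass(frozen=True)
class BatchDesign:
    """Sample-to-batch assignment, optionally with biological group labels."""

    batch: pd.Series  # sample_id -> batch label
    group: pd.Series | None = None  # sample_id -> group label

    @classmethod
    def from_mapping(cls, mapping: pd.DataFrame, batch: pd.Series | None = None) -> "BatchDesign":
        m = mapping.set_index("sample_id")
        if batch is None:
            if "batch" not in m.columns:
                raise ValueError("mapping has no batch column and none was given")
            batch = m["batch"]
        group = m["group"] if "group" in m.columns else None
        return cls(batch=batch, group=group)

    def validate(self, expr: pd.DataFrame, min_batch_size: int = 2) -> None:
        missing = [s for s in expr.columns if s not in self.batch.index]
        if missing:
            raise ValueError(f"samples without batch label: {missing[:5]}")
        counts = self.batch.loc[list(expr.columns)].value_counts()
        small = counts[counts < min_batch_size]
        if len(small):
            raise ValueError(
                f"batches with fewer than {min_batch_size} samples: "
                f"{sorted(small.index)}"
            )


def adjust_location_scale(
    expr: pd.DataFrame, design: BatchDesign, preserve_groups: bool = True
) -> pd.DataFrame:
    """Baseline two-moment batch adjuster.

    Per gene, each batch's values are standardized by the batch mean and sd
    and rescaled to the grand mean and the pooled within-batch sd, so all
    batches end up with identical per-gene first and second moments. With
    ``preserve_groups`` (and a group label available) the batch moments are
    estimated on group-centered residuals, so biological group differences
    survive the adjustment. A batch with zero sd for some gene is recentered
    only. The per-gene mean over all samples is preserved exactly, and the
    transform is idempotent.
    """
    design.validate(expr)
    samples = list(expr.columns)
    x = expr.to_numpy(dtype=float)
    batches = design.batch.loc[samples].to_numpy()

    if preserve_groups and design.group is not None:
        groups = design.group.loc[samples].to_numpy()
        group_means = np.zeros_like(x)
        for g in np.unique(groups):
            idx = np.flatnonzero(groups == g)
            group_means[:, idx] = x[:, idx].mean(axis=1, keepdims=True)
        r = x - group_means
    else:
        group_means = np.zeros_like(x)
        r = x

    labels = np.unique(batches)
    if len(labels) == 1:
        return expr.copy()

    grand = r.mean(axis=1, keepdims=True)
    batch_idx = {b: np.flatnonzero(batches == b) for b in labels}
    mus = {b: r[:, idx].mean(axis=1, keepdims=True) for b, idx in batch_idx.items()}
    sds = {b: r[:, idx].std(axis=1, ddof=1, keepdims=True) for b, idx in batch_idx.items()}
    # pooled within-batch sd; using it (not the overall sd) as the target
    # scale makes the transform exactly idempotent
    num = sum((len(idx) - 1) * sds[b] ** 2 for b, idx in batch_idx.items())
    den = sum(len(idx) - 1 for idx in batch_idx.values())
    pooled_sd = np.sqrt(num / den)

    out = np.empty_like(r)
    for b, idx in batch_idx.items():
        centered = r[:, idx] - mus[b]
        scale = np.divide(
            pooled_sd, sds[b], out=np.ones_like(pooled_sd), where=sds[b] > 0
        )
        out[:, idx] = grand + centered * scale
    return pd.DataFrame(out + group_means, index=expr.index, columns=expr.columns)


# --- adjuster registry ------------------------------------------------------

Adjuster = Callable[[pd.DataFrame, BatchDesign], pd.DataFrame]

_REGISTRY: dict[str, Adjuster] = {}


def register_adjuster(name: str, fn: Adjuster, overwrite: bool = False) -> None:
    """Register a batch adjuster under ``name``.

    An adjuster maps ``(expr, design) -> expr`` with an unchanged gene and
    sample roster; the contract is checked at call time by
    :func:`apply_adjuster`.
    """
    if name in _REGISTRY and not overwrite:
        raise ValueError(f"adjuster {name!r} already registered")
    _REGISTRY[name] = fn


def list_adjusters() -> list[str]:
    return sorted(_REGISTRY)


def get_adjuster(name: str) -> Adjuster:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown adjuster {name!r}; known: {list_adjusters()}"
        ) from None


def apply_adjuster(
    adjuster: str | Adjuster, expr: pd.DataFrame, design: BatchDesign
) -> pd.DataFrame:
    """Run an adjuster (by name or callable) and enforce its contract."""
    fn = get_adjuster(adjuster) if isinstance(adjuster, str) else adjuster
    out = fn(expr, design)
    if list(out.index) != list(expr.index) or list(out.columns) != list(expr.columns):
        raise ValueError(
            "adjuster contract violation: gene/sample roster changed"
        )
    return out


def _identity(expr: pd.DataFrame, design: BatchDesign) -> pd.DataFrame:
    return expr.copy()


register_adjuster("identity", _identity)
register_adjuster("location_scale", adjust_location_scale)


def make_oracle_adjuster(noise: pd.DataFrame) -> Adjuster:
    """Adjuster that subtracts a known injected perturbation exactly.

    ``noise`` holds, per gene x sample, the perturbation that was added
    (zero for clean samples). Only meaningful in simulations where the
    injected noise is recorded; serves as the upper bound every real
    adjuster is compared against.
    """

    def oracle(expr: pd.DataFrame, design: BatchDesign) -> pd.DataFrame:
        aligned = noise.reindex(index=expr.index, columns=expr.columns)
        if aligned.isna().any().any():
            raise ValueError("noise matrix does not cover the expression roster")
        return expr - aligned

    return oracle
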