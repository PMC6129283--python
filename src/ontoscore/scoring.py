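"""Per-sample ontology scores and grouped comparisons.

The ontology score of sample k is

    u_k = cor(D[:, k], O[:, k])

the correlation between the sample's observed similarities to all samples
(column k of the expression-derived matrix D) and its expected similarities
(column k of the ontology-derived matrix O). High u_k means the expression
neighbourhood of the sample looks the way its ontology annotation predicts.
"""

from __future__ import annotations

import warnings
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

CORRELATIONS = ("spearman", "pearson")

_SUMMARY_COLUMNS = ["n", "n_na", "mean", "median", "q25", "q75"]


def align(D: pd.DataFrame, O: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict D and O to their shared samples, in D's order.

    Warns about dropped samples; requires at least 3 shared samples.
    """
    in_o = set(O.index)
    shared = [s for s in D.index if s in in_o]
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} shared samples between D and O; need >= 3"
        )
    dropped = (len(D.index) - len(shared)) + (len(O.index) - len(shared))
    if dropped:
        warnings.warn(f"align dropped {dropped} unshared sample(s)", stacklevel=2)
    return D.loc[shared, shared], O.loc[shared, shared]


def _corr(x: np.ndarray, y: np.ndarray, cor: str) -> float:
    if cor == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    return float(stats.pearsonr(x, y).statistic)


def ontology_score(
    D: pd.DataFrame,
    O: pd.DataFrame,
    cor: str = "spearman",
    include_self: bool = True,
) -> pd.DataFrame:
    """Compute the per-sample score vector u from matched matrices D and O.

    D and O must cover the same samples in the same order (use
    :func:`align` first; a mismatch is an error, never silently reordered).
    Entries where either matrix is NA are dropped pairwise; with
    ``include_self=False`` the self-pair (always (1, 1)) is dropped too.
    A score computed on fewer than 3 pairs, or against a constant column,
    is NA.

    Returns a frame indexed by sample id with columns ``score`` and
    ``n_pairs_used``.
    """
    if cor not in CORRELATIONS:
        raise ValueError(f"cor must be one of {CORRELATIONS}, got {cor!r}")
    if list(D.index) != list(O.index) or list(D.columns) != list(O.columns):
        raise ValueError("D and O sample order differs; call align() first")
    dv = D.to_numpy(dtype=float)
    ov = O.to_numpy(dtype=float)
    n = dv.shape[0]
    scores = np.full(n, np.nan)
    n_pairs = np.zeros(n, dtype=int)
    for k in range(n):
        mask = np.isfinite(dv[:, k]) & np.isfinite(ov[:, k])
        if not include_self:
            mask[k] = False
        d = dv[mask, k]
        o = ov[mask, k]
        n_pairs[k] = d.size
        if d.size < 3:
            continue
        if np.ptp(d) == 0 or np.ptp(o) == 0:
            continue  # constant column: correlation undefined
        scores[k] = _corr(d, o, cor)
    n_na = int(np.isnan(scores).sum())
    if n_na:
        warnings.warn(f"{n_na} of {n} ontology scores are NA", stacklevel=2)
    return pd.DataFrame(
        {"score": scores, "n_pairs_used": n_pairs}, index=list(D.index)
    )


def _summary(values: pd.Series) -> pd.Series:
    defined = values.dropna()
    return pd.Series(
        {
            "n": len(values),
            "n_na": len(values) - len(defined),
            "mean": defined.mean(),
            "median": defined.median(),
            "q25": defined.quantile(0.25),
            "q75": defined.quantile(0.75),
        }
    )


def group_scores(
    scores: pd.DataFrame, mapping: pd.DataFrame, by: str = "group"
) -> pd.DataFrame:
    """Summarise scores per group, batch, or group x batch combination.

    ``by`` is one of ``"group"``, ``"batch"``, ``"group_x_batch"``. Every
    scored sample must carry the requested label(s).
    """
    keys = {"group": ["group"], "batch": ["batch"], "group_x_batch": ["group", "batch"]}
    if by not in keys:
        raise ValueError(f"by must be one of {sorted(keys)}, got {by!r}")
    flat = scores.drop(
        columns=[c for c in ("term_id", "group", "batch") if c in scores.columns]
    )
    table = flat.reset_index(names="sample_id").merge(
        mapping, on="sample_id", how="left"
    )
    for col in keys[by]:
        if col not in table.columns or table[col].isna().any():
            missing = (
                list(table["sample_id"])
                if col not in table.columns
                else sorted(table.loc[table[col].isna(), "sample_id"])
            )
            raise ValueError(
                f"samples without a {col!r} label: {missing[:5]}"
                + ("..." if len(missing) > 5 else "")
            )
    out = (
        table.groupby(keys[by], sort=True)["score"].apply(_summary).unstack()
    )
    out = out[_SUMMARY_COLUMNS]
    out[["n", "n_na"]] = out[["n", "n_na"]].astype(int)
    return out.reset_index()


class RankSumResult(NamedTuple):
    statistic: float
    pvalue: float
    method: str


def compare_score_groups(u_a, u_b) -> RankSumResult:
    """Two-sided Wilcoxon–Mann–Whitney rank-sum test between two score sets.

    Uses the exact null distribution for small tie-free samples and the
    normal approximation with tie correction otherwise. NA scores are
    dropped; each group needs at least 3 defined values.
    """
    a = np.asarray(pd.Series(u_a).dropna(), dtype=float)
    b = np.asarray(pd.Series(u_b).dropna(), dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs >= 3 defined scores")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        warnings.warn("all scores tied across both groups; p = 1", stacklevel=2)
        return RankSumResult(statistic=a.size * b.size / 2.0, pvalue=1.0, method="tied")
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size <= 25 and b.size <= 25 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return RankSumResult(
        statistic=float(res.statistic), pvalue=float(res.pvalue), method=method
    )
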