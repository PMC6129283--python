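"""Expression preprocessing, PCA embedding, and the observed similarity matrix.

The observed sample-similarity matrix D is built in three steps: optional
log-transform of the genes x samples matrix, projection of samples onto the
leading principal components, and pairwise rank (or product-moment)
correlation between the samples' component coordinate vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

CORRELATIONS = ("spearman", "pearson")


def _as_float_matrix(expr: pd.DataFrame) -> np.ndarray:
    values = expr.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("expression matrix contains non-finite values")
    return values


def preprocess(
    expr: pd.DataFrame, log_transform: bool = True, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Optionally log2-transform a non-negative genes x samples matrix.

    ``log_transform`` applies ``log2(x + pseudocount)`` elementwise; with
    the default pseudocount of 1 a zero stays zero. Negative values are
    rejected when the transform is requested (the log would be undefined);
    with the flag off the input is returned unchanged (as a copy), so
    already-transformed or artificially perturbed matrices pass through.
    """
    values = _as_float_matrix(expr)
    if not log_transform:
        return expr.copy()
    if (values < 0).any():
        raise ValueError("expression values must be non-negative")
    return pd.DataFrame(
        np.log2(values + pseudocount), index=expr.index, columns=expr.columns
    )


@dataclass(frozen=True)
class PCEmbedding:
    """Samples projected onto leading principal components.

    ``scores`` is samples x n_pcs; ``explained_variance_fraction`` gives,
    per retained component, its share of the total variance (non-increasing,
    summing to at most 1 over all components).
    """

    sample_ids: tuple
    scores: np.ndarray
    explained_variance_fraction: np.ndarray

    @property
    def n_pcs(self) -> int:
        return self.scores.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.n_pcs)]
        return pd.DataFrame(self.scores, index=list(self.sample_ids), columns=cols)


def pca_embed(expr: pd.DataFrame, n_pcs: int = 4, center: bool = True) -> PCEmbedding:
    """Project samples onto the top ``n_pcs`` principal axes.

    PCA is computed by SVD of the (gene-centered, unless ``center=False``)
    samples x genes matrix. The result is deterministic: each component's
    sign is fixed so that its largest-magnitude gene loading is positive.
    """
    values = _as_float_matrix(expr)
    x = values.T  # samples x genes
    n_samples, n_genes = x.shape
    if n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    limit = min(n_samples - 1, n_genes) if center else min(n_samples, n_genes)
    if not 1 <= n_pcs <= limit:
        raise ValueError(f"n_pcs must be in [1, {limit}], got {n_pcs}")
    if center:
        x = x - x.mean(axis=0)
    total_var = float(np.sum(x**2))
    if total_var == 0.0:
        raise ValueError("expression matrix has no variance; PCA undefined")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # sign convention: largest-|loading| gene positive on every component
    for j in range(n_pcs):
        i = int(np.argmax(np.abs(vt[j])))
        if vt[j, i] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    scores = u[:, :n_pcs] * s[:n_pcs]
    evf = (s[:n_pcs] ** 2) / np.sum(s**2)
    return PCEmbedding(
        sample_ids=tuple(expr.columns),
        scores=scores,
        explained_variance_fraction=evf,
    )


def observed_similarity_matrix(
    embedding: PCEmbedding, cor: str = "spearman"
) -> pd.DataFrame:
    """Observed sample-similarity matrix D from PC coordinates.

    Entry (k, l) is the correlation between the two samples' length-n_pcs
    score vectors (average ranks for ties under Spearman). The diagonal is
    forced to exactly 1 except for samples with a constant score vector,
    whose correlations are undefined and reported as NA with a warning.
    """
    if cor not in CORRELATIONS:
        raise ValueError(f"cor must be one of {CORRELATIONS}, got {cor!r}")
    if embedding.n_pcs < 2:
        raise ValueError("need at least 2 PCs to correlate coordinate vectors")
    coords = pd.DataFrame(embedding.scores.T, columns=list(embedding.sample_ids))
    d = coords.corr(method=cor)
    constant = coords.std(axis=0, ddof=0).to_numpy() == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} sample(s) have constant PC scores; "
            "their similarities are NA",
            stacklevel=2,
        )
    diag = np.where(constant, np.nan, 1.0)
    values = d.to_numpy()
    values[np.diag_indices_from(values)] = diag
    return pd.DataFrame(values, index=d.index, columns=d.columns)
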