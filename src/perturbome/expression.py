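"""Expression-matrix construction: FPKM, log transform, global normalization,
common-gene restriction, and sample ordination (hierarchical clustering, PCA).

Matrices are pandas DataFrames with genes as rows and samples as columns.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

__all__ = [
    "compute_fpkm",
    "global_normalize_log",
    "GlobalLogNormalizer",
    "common_gene_subset",
    "sample_clustering",
    "sample_pca",
]


def compute_fpkm(counts: pd.DataFrame, gene_lengths: Sequence[float]) -> pd.DataFrame:
    """Convert read counts to FPKM.

    FPKM = count * 1e9 / (gene_length_bp * total_counts_of_sample).
    """
    lengths = np.asarray(gene_lengths, dtype=float)
    if lengths.shape[0] != counts.shape[0]:
        raise ValueError("gene_lengths must match the number of gene rows")
    if np.any(lengths <= 0):
        raise ValueError("zero or negative gene length")
    totals = counts.sum(axis=0).to_numpy(dtype=float)
    if np.any(totals <= 0):
        raise ValueError("sample with non-positive total counts")
    fpkm = counts.to_numpy(dtype=float) * 1e9 / (lengths[:, None] * totals[None, :])
    return pd.DataFrame(fpkm, index=counts.index, columns=counts.columns)


class GlobalLogNormalizer(BaseEstimator, TransformerMixin):
    """log10 transform with a per-sample additive shift to a common mean.

    Transforms linear FPKM to ``log10(fpkm + pseudocount)`` and then shifts
    every sample (column) so its mean equals the grand mean over all samples
    seen at fit time — "global normalization to an identical mean value in
    the logarithmic scale".

    Parameters
    ----------
    pseudocount : float or "auto"
        Offset added before the log.  ``"auto"`` uses the smallest nonzero
        FPKM value of the fitted data.

    Attributes
    ----------
    pseudocount_ : float
        Resolved pseudocount.
    target_mean_ : float
        Grand mean of the log matrix; every sample is shifted onto it.
    """

    def __init__(self, pseudocount: float | str = "auto"):
        self.pseudocount = pseudocount

    def _as_array(self, X) -> np.ndarray:
        arr = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
        if np.any(arr < 0):
            raise ValueError("FPKM values must be non-negative")
        return arr

    def fit(self, X, y=None):
        arr = self._as_array(X)
        if np.any(arr.sum(axis=0) == 0):
            raise ValueError("all-zero sample")
        if self.pseudocount == "auto":
            nonzero = arr[arr > 0]
            self.pseudocount_ = float(nonzero.min()) if nonzero.size else 1.0
        else:
            self.pseudocount_ = float(self.pseudocount)
        log = np.log10(arr + self.pseudocount_)
        self.target_mean_ = float(log.mean())
        return self

    def transform(self, X):
        arr = self._as_array(X)
        log = np.log10(arr + self.pseudocount_)
        shifted = log + (self.target_mean_ - log.mean(axis=0))[None, :]
        if isinstance(X, pd.DataFrame):
            return pd.DataFrame(shifted, index=X.index, columns=X.columns)
        return shifted


def global_normalize_log(
    fpkm: pd.DataFrame, pseudocount: float | str = "auto"
) -> pd.DataFrame:
    """Log10-transform FPKM and equalize per-sample means (grand mean)."""
    return GlobalLogNormalizer(pseudocount=pseudocount).fit_transform(fpkm)


def common_gene_subset(
    matrix: pd.DataFrame, gene_sets: Iterable[Iterable[str]]
) -> pd.DataFrame:
    """Restrict to genes present in every genome's gene set.

    Row order of ``matrix`` (the reference genome) is preserved.
    """
    common = None
    for s in gene_sets:
        s = set(s)
        common = s if common is None else common & s
    if common is None:
        return matrix
    keep = [g for g in matrix.index if g in common]
    if not keep:
        raise ValueError("empty gene intersection")
    return matrix.loc[keep]


def sample_clustering(expr: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Ward (ward.D2) clustering of samples on 1 − Spearman correlation.

    Returns the scipy linkage matrix and the leaf labels in dendrogram
    order (deterministic; scipy's leaf ordering with labels as tie-break
    applied up front by sorting columns).
    """
    if expr.shape[1] < 2:
        raise ValueError("need at least two samples")
    expr = expr[sorted(expr.columns)]
    arr = expr.to_numpy(dtype=float)
    if np.any(arr.std(axis=0) == 0):
        bad = expr.columns[np.flatnonzero(arr.std(axis=0) == 0)[0]]
        raise ValueError(f"constant sample profile: {bad}")
    rho = spearmanr(arr).statistic
    rho = np.atleast_2d(rho)
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    # scipy's "ward" on a precomputed condensed matrix is the ward.D2 update
    link = hierarchy.linkage(squareform(dist, checks=False), method="ward")
    order = hierarchy.leaves_list(link)
    return link, [expr.columns[i] for i in order]


def sample_pca(expr: pd.DataFrame, n_components: int | None = None):
    """Centered, unscaled PCA of samples (genes are features).

    Sign convention: each component's largest-magnitude gene loading is
    positive.  Returns ``(scores, explained_variance_ratio)`` with scores
    indexed by sample.
    """
    X = expr.to_numpy(dtype=float).T  # samples x genes
    n_comp = n_components or min(X.shape)
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(X)
    for k in range(pca.components_.shape[0]):
        j = np.argmax(np.abs(pca.components_[k]))
        if pca.components_[k, j] < 0:
            pca.components_[k] *= -1
            scores[:, k] *= -1
    scores = pd.DataFrame(
        scores,
        index=expr.columns,
        columns=[f"PC{i+1}" for i in range(scores.shape[1])],
    )
    return scores, pca.explained_variance_ratio_
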