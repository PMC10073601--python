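"""Weighted co-expression modules: soft-thresholded adjacency, topological
overlap, tree-cut module detection, eigengene merging, module-trait
correlation, and conserved/responsive/epistatic classification.

The network is unsigned: adjacency a_ij = |cor(g_i, g_j)|^beta (Pearson,
across samples).  The topological overlap TOM_ij =
(l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with l_ij = sum_u a_iu a_uj over
u != i, j and k_i the connectivity, measures shared neighborhood; modules
are branches of the average-linkage tree on 1 - TOM.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

__all__ = [
    "pick_soft_power",
    "scale_free_fit",
    "tom_from_expression",
    "detect_modules",
    "module_eigengene",
    "merge_modules",
    "module_trait_correlation",
    "classify_modules",
    "CoexpressionModules",
]


def _gene_correlation(expr: pd.DataFrame) -> np.ndarray:
    arr = expr.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    if np.any(sd == 0):
        bad = expr.index[np.flatnonzero(sd == 0)[0]]
        raise ValueError(f"constant gene: {bad}")
    c = np.corrcoef(arr)
    return np.clip(c, -1.0, 1.0)


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the scale-free topology fit.

    log10 of the empirical frequency p(k) is regressed on log10 of the mean
    connectivity over equal-occupancy bins; the R^2 carries the sign of the
    (negated) slope, so only decreasing p(k) counts as scale-free.
    """
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if k.size < 4:
        raise ValueError("too few positive connectivities")
    edges = np.quantile(k, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    if len(edges) < 3:
        raise ValueError("fewer than 2 nonempty connectivity bins")
    idx = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, len(edges) - 2)
    nonempty = [b for b in range(len(edges) - 1) if (idx == b).any()]
    if len(nonempty) < 2:
        raise ValueError("fewer than 2 nonempty connectivity bins")
    mean_k = np.array([k[idx == b].mean() for b in nonempty])
    # equal-occupancy bins: the density p(k) is the bin frequency divided by
    # the bin width, otherwise every bin would have the same mass
    width = np.array([edges[b + 1] - edges[b] for b in nonempty])
    density = np.array([(idx == b).mean() for b in nonempty]) / np.maximum(width, 1e-12)
    lx, ly = np.log10(mean_k), np.log10(density)
    slope, _, r, _, _ = stats.linregress(lx, ly)
    return float(-np.sign(slope) * r**2)


def pick_soft_power(
    expr: pd.DataFrame,
    r2_target: float = 0.9,
    candidate_powers: tuple = tuple(range(1, 21)),
) -> tuple[int, float, bool]:
    """Smallest soft-threshold power reaching the scale-free R^2 target.

    Returns ``(beta, r2, reached)``; if no candidate reaches the target,
    the power with maximal R^2 is returned with ``reached=False``.
    """
    if expr.shape[1] < 4:
        raise ValueError("need at least four samples")
    if r2_target <= 0:
        return int(candidate_powers[0]), 0.0, True
    c = np.abs(_gene_correlation(expr))
    best = None
    for beta in candidate_powers:
        a = c**beta
        k = a.sum(axis=0) - 1.0  # exclude self
        r2 = scale_free_fit(k)
        if r2 >= r2_target:
            return int(beta), float(r2), True
        if best is None or r2 > best[1]:
            best = (int(beta), float(r2))
    return best[0], best[1], False


def tom_from_expression(expr: pd.DataFrame, beta: int = 12) -> np.ndarray:
    """Topological overlap matrix from genes x samples log expression."""
    if expr.shape[1] < 3:
        raise ValueError("need at least three samples")
    if beta < 1:
        raise ValueError("beta must be >= 1")
    a = np.abs(_gene_correlation(expr)) ** beta
    np.fill_diagonal(a, 1.0)
    aa = a @ a
    # l_ij = sum_{u != i,j} a_iu a_uj  (a_ii = 1)
    l = aa - 2.0 * a
    k = a.sum(axis=0) - 1.0
    denom = np.minimum.outer(k, k) + 1.0 - a
    np.fill_diagonal(denom, 1.0)  # diagonal is overwritten below; avoid 0/0
    tom = (l + a) / denom
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def detect_modules(tom: np.ndarray, min_module_size: int = 50) -> np.ndarray:
    """Cut the average-linkage tree of 1 - TOM into modules.

    The static cut height is chosen adaptively: over the grid of merge
    heights, the cut maximizing the number of clusters of at least
    ``min_module_size`` wins (ties go to the largest such height, which
    leaves the fewest genes unassigned).  Clusters below the size floor are
    assigned to module 0; labels 1.. are ordered by decreasing size.
    """
    tom = np.asarray(tom, dtype=float)
    if not np.allclose(tom, tom.T, atol=1e-8):
        raise ValueError("TOM must be symmetric")
    d = 1.0 - tom
    np.fill_diagonal(d, 0.0)
    link = hierarchy.linkage(squareform(d, checks=False), method="average")
    heights = np.unique(link[:, 2])
    # cap candidate cuts at 99% of the tree height: branches only joined at
    # the very top (e.g. an unstructured network collapsing into one blob)
    # must not count as a module
    capped = heights[heights <= 0.99 * heights.max()]
    if capped.size:
        heights = capped
    best_labels, best_count, best_h = np.zeros(tom.shape[0], dtype=int), -1, -1.0
    for h in heights:
        cut = h + 1e-12
        labels = hierarchy.fcluster(link, t=cut, criterion="distance")
        sizes = np.bincount(labels)
        count = int((sizes[1:] >= min_module_size).sum())
        if count > best_count or (count == best_count and h > best_h):
            best_labels, best_count, best_h = labels, count, h
    return _relabel_by_size(best_labels, min_module_size)


def _relabel_by_size(raw: np.ndarray, min_module_size: int) -> np.ndarray:
    """Keep clusters >= min size, labels 1.. by decreasing size, rest 0."""
    out = np.zeros(raw.shape[0], dtype=int)
    ids, sizes = np.unique(raw, return_counts=True)
    keep = ids[sizes >= min_module_size]
    order = keep[np.argsort(-sizes[sizes >= min_module_size], kind="stable")]
    for new, old in enumerate(order, start=1):
        out[raw == old] = new
    return out


def module_eigengene(expr: pd.DataFrame, module_genes) -> np.ndarray:
    """First principal component of the module's standardized expression.

    Per-gene z-scores across samples feed an SVD; the eigengene is the
    first left singular vector scaled to unit variance, sign-aligned so its
    correlation with the module's mean expression profile is positive.
    """
    sub = expr.loc[module_genes]
    if sub.shape[0] < 2:
        raise ValueError("module needs at least two genes")
    arr = sub.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    if np.all(sd == 0):
        raise ValueError("singular module: all genes constant")
    z = (arr - arr.mean(axis=1, keepdims=True)) / np.where(sd == 0, 1.0, sd)[:, None]
    u, s, _ = np.linalg.svd(z.T, full_matrices=False)
    e = u[:, 0]
    if e.std() == 0:
        raise ValueError("degenerate eigengene")
    e = e / e.std()
    mean_profile = z.mean(axis=0)
    if np.dot(e, mean_profile - mean_profile.mean()) < 0:
        e = -e
    return e


def _eigengene_frame(expr: pd.DataFrame, labels: np.ndarray) -> pd.DataFrame:
    mods = [m for m in np.unique(labels) if m != 0]
    data = {
        f"M{m}": module_eigengene(expr, expr.index[labels == m]) for m in mods
    }
    return pd.DataFrame(data, index=expr.columns)


def merge_modules(
    expr: pd.DataFrame, labels: np.ndarray, merge_height: float = 0.25
) -> np.ndarray:
    """Merge modules whose eigengenes are closer than ``merge_height``.

    Iteratively merges the closest pair with eigengene dissimilarity
    (1 - Pearson correlation) below the cut, recomputing eigengenes after
    every merge, until no pair qualifies.  Labels are re-ordered by size.
    """
    labels = np.asarray(labels, dtype=int).copy()
    while True:
        mods = [m for m in np.unique(labels) if m != 0]
        if len(mods) < 2:
            break
        eg = np.column_stack(
            [module_eigengene(expr, expr.index[labels == m]) for m in mods]
        )
        c = np.corrcoef(eg.T)
        diss = 1.0 - c
        np.fill_diagonal(diss, np.inf)
        i, j = np.unravel_index(np.argmin(diss), diss.shape)
        if diss[i, j] >= merge_height:
            break
        labels[labels == mods[j]] = mods[i]
    # renumber by decreasing size, module 0 untouched
    out = np.zeros_like(labels)
    ids, sizes = np.unique(labels[labels != 0], return_counts=True)
    for new, old in enumerate(ids[np.argsort(-sizes, kind="stable")], start=1):
        out[labels == old] = new
    return out


def module_trait_correlation(
    eigengenes: pd.DataFrame, trait, alpha: float = 0.01
) -> pd.DataFrame:
    """Pearson correlation of each eigengene with a per-sample trait.

    Returns r, the two-sided t-distribution p, and a significance flag at
    ``alpha`` (growth-rate correlations use p < 0.01).
    """
    t = np.asarray(trait, dtype=float)
    if t.std() == 0:
        raise ValueError("constant trait")
    rows = []
    for m in eigengenes.columns:
        r, p = stats.pearsonr(eigengenes[m].to_numpy(), t)
        rows.append((m, r, p, p < alpha))
    return pd.DataFrame(rows, columns=["module", "r", "p", "significant"]).set_index(
        "module"
    )


def classify_modules(
    enrich_table: pd.DataFrame,
    single_contrasts: tuple = ("dG", "dS", "dE"),
    dual_contrasts: tuple = ("dGS", "dGE", "dES"),
    stress_contrast: str = "dS",
    stress_duals: tuple = ("dGS", "dES"),
) -> pd.Series:
    """Classify modules as conserved / responsive / epistatic.

    conserved: enriched for DEGs in no contrast.  epistatic: enriched in
    the single stress contrast but in neither stress-containing dual (the
    enrichment vanishes under dual perturbation).  responsive: enriched in
    at least one contrast and not epistatic.

    ``enrich_table`` is the (module, contrast)-indexed table from
    :func:`perturbome.enrichment.module_deg_enrichment`.
    """
    required = set(single_contrasts) | set(dual_contrasts)
    present = set(enrich_table.index.get_level_values("contrast"))
    missing = sorted(required - present)
    if missing:
        raise ValueError(f"missing contrasts: {', '.join(missing)}")
    out = {}
    for module in enrich_table.index.get_level_values("module").unique():
        sub = enrich_table.xs(module, level="module")
        sig = set(sub.index[sub["significant"]])
        if not sig:
            out[module] = "conserved"
        elif stress_contrast in sig and not (sig & set(stress_duals)):
            out[module] = "epistatic"
        else:
            out[module] = "responsive"
    return pd.Series(out, name="class")


class CoexpressionModules(ClusterMixin, BaseEstimator):
    """Co-expression module detection as a clustering estimator.

    fit() consumes a samples x genes matrix (sklearn orientation) and
    clusters the *genes*: adjacency |cor|^beta, TOM, average-linkage tree
    cut, eigengene merging.

    Parameters
    ----------
    soft_power : int
        Soft-threshold exponent beta (adjacency = |cor|^beta).
    min_module_size : int
        Smallest retained module.
    merge_height : float
        Eigengene-dissimilarity cut below which modules merge.

    Attributes
    ----------
    labels_ : ndarray of int, one per gene (0 = unassigned)
    eigengenes_ : DataFrame, samples x modules (M1, M2, ... by size)
    module_sizes_ : dict
    """

    def __init__(
        self,
        soft_power: int = 12,
        min_module_size: int = 50,
        merge_height: float = 0.25,
    ):
        self.soft_power = soft_power
        self.min_module_size = min_module_size
        self.merge_height = merge_height

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        expr = X.T  # genes x samples
        tom = tom_from_expression(expr, beta=self.soft_power)
        labels = detect_modules(tom, min_module_size=self.min_module_size)
        labels = merge_modules(expr, labels, merge_height=self.merge_height)
        self.labels_ = labels
        self.eigengenes_ = _eigengene_frame(expr, labels)
        ids, sizes = np.unique(labels[labels != 0], return_counts=True)
        self.module_sizes_ = {f"M{m}": int(s) for m, s in zip(ids, sizes)}
        self.gene_index_ = expr.index
        return self

    def module_members(self) -> dict[str, set]:
        """Gene sets per module (excluding the unassigned pool)."""
        return {
            f"M{m}": set(self.gene_index_[self.labels_ == m])
            for m in np.unique(self.labels_)
            if m != 0
        }

    def correlate_trait(self, trait, alpha: float = 0.01) -> pd.DataFrame:
        return module_trait_correlation(self.eigengenes_, trait, alpha=alpha)
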