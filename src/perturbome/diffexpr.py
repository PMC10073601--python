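"""Rank Product differential expression.

For a two-class comparison with nA and nB replicates, every one-vs-one
cross-replicate pair (K = nA*nB comparisons) ranks the genes by log
fold-change; the Rank Product of a gene is the geometric mean of its ranks
across comparisons (rank 1 = most extreme).  Significance comes from a
permutation null (random within-comparison rank assignments): p is the
fraction of null Rank Products at least as extreme, and the proportion of
false predictions pfp = p * n_genes / rank-position, made monotone by a
step-up pass.  Up- and down-regulation are scored separately.

A per-gene Welch t-test with Benjamini-Hochberg adjustment is included as a
simple parametric substitute route; it is not a count-model DE method.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "RankProdResult",
    "DEGSet",
    "rank_product_stat",
    "rankprod_significance",
    "call_degs",
    "deg_overlap",
    "welch_bh_test",
    "RankProductDE",
]


@dataclass
class RankProdResult:
    """Rank Product statistics (and, once computed, significance) per gene."""

    genes: pd.Index
    rp_up: np.ndarray
    rp_down: np.ndarray
    n_comparisons: int
    # sum of log ranks; the comparison scale used against the null
    _logsum_up: np.ndarray = field(repr=False, default=None)
    _logsum_down: np.ndarray = field(repr=False, default=None)
    p_up: np.ndarray | None = None
    p_down: np.ndarray | None = None
    pfp_up: np.ndarray | None = None
    pfp_down: np.ndarray | None = None
    n_permutations: int | None = None
    seed: int | None = None

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def to_frame(self) -> pd.DataFrame:
        cols = {"rp_up": self.rp_up, "rp_down": self.rp_down}
        for name in ("p_up", "p_down", "pfp_up", "pfp_down"):
            v = getattr(self, name)
            if v is not None:
                cols[name] = v
        return pd.DataFrame(cols, index=self.genes)


@dataclass
class DEGSet:
    """Differentially expressed genes of one contrast."""

    contrast: str
    genes: list[str]
    direction: dict[str, str]  # gene -> "up" | "down"
    method: str
    threshold: float
    universe: frozenset = field(repr=False, default_factory=frozenset)


def rank_product_stat(expr_a: pd.DataFrame, expr_b: pd.DataFrame) -> RankProdResult:
    """Rank Products for the contrast A -> B (up = higher in B).

    Both inputs are genes x replicates on the log scale, with identical
    gene index.  Ties in fold change receive average ranks.
    """
    if not expr_a.index.equals(expr_b.index):
        raise ValueError("gene indexes must match")
    if expr_a.shape[1] < 1 or expr_b.shape[1] < 1:
        raise ValueError("need at least one replicate per side")
    a = expr_a.to_numpy(dtype=float)
    b = expr_b.to_numpy(dtype=float)
    n = a.shape[0]
    logsum_up = np.zeros(n)
    logsum_down = np.zeros(n)
    k = 0
    for i in range(a.shape[1]):
        for j in range(b.shape[1]):
            fc = b[:, j] - a[:, i]
            r_up = stats.rankdata(-fc)  # rank 1 = most up-regulated in B
            r_down = stats.rankdata(fc)
            logsum_up += np.log(r_up)
            logsum_down += np.log(r_down)
            k += 1
    return RankProdResult(
        genes=expr_a.index,
        rp_up=np.exp(logsum_up / k),
        rp_down=np.exp(logsum_down / k),
        n_comparisons=k,
        _logsum_up=logsum_up,
        _logsum_down=logsum_down,
    )


def _step_up_pfp(p: np.ndarray) -> np.ndarray:
    """pfp = p * n / rank-position, monotone after a step-up pass."""
    n = p.size
    order = np.argsort(p, kind="stable")
    pfp_sorted = p[order] * n / np.arange(1, n + 1)
    pfp_sorted = np.minimum.accumulate(pfp_sorted[::-1])[::-1]
    out = np.empty(n)
    out[order] = pfp_sorted
    return out


def _null_logsums_permutation(
    n_genes: int, k: int, n_permutations: int, rng: np.random.Generator
) -> np.ndarray:
    """Pooled null sum-of-log-ranks from random rank assignments."""
    logranks = np.log(np.arange(1, n_genes + 1, dtype=float))
    out = np.empty((n_permutations, n_genes))
    for p in range(n_permutations):
        s = np.zeros(n_genes)
        for _ in range(k):
            s += logranks[rng.permutation(n_genes)]
        out[p] = s
    return np.sort(out.ravel())


def _null_logsums_exact(n_genes: int, k: int) -> np.ndarray:
    """All n^K sums of log ranks of K independent uniform ranks.

    Within one permutation the ranks of different genes are dependent, but
    each single gene's rank vector across the K comparisons is uniform on
    {1..n}^K, and the pooled null over genes coincides with that product
    distribution, so exhaustive enumeration is over n^K states.
    """
    if n_genes**k > 2_000_000:
        raise ValueError("exact enumeration infeasible; use the permutation mode")
    logranks = np.log(np.arange(1, n_genes + 1, dtype=float))
    sums = [
        sum(tup) for tup in itertools.product(logranks, repeat=k)
    ]
    return np.sort(np.asarray(sums))


def rankprod_significance(
    result: RankProdResult,
    n_permutations: int = 1000,
    seed: int | None = None,
    method: str = "permutation",
) -> RankProdResult:
    """Attach permutation (or exhaustive) p and pfp estimates to ``result``.

    ``method="permutation"``: p = (#null <= observed + 1) / (N + 1) with
    N = n_permutations * n_genes pooled null values (never exactly zero).
    ``method="exact"``: exhaustive enumeration of the per-gene null,
    p = #null <= observed / n^K, feasible for small matrices.
    """
    n, k = result.n_genes, result.n_comparisons
    if method == "exact":
        null = _null_logsums_exact(n, k)
        denom = null.size
        offset = 0
    elif method == "permutation":
        if n_permutations < 100:
            raise ValueError("need at least 100 permutations for stable estimates")
        rng = np.random.default_rng(seed)
        null = _null_logsums_permutation(n, k, n_permutations, rng)
        denom = null.size + 1
        offset = 1
    else:
        raise ValueError(f"unknown method: {method}")
    eps = 1e-9  # guard against log round-off flipping exact ties
    p_up = (np.searchsorted(null, result._logsum_up + eps, side="right") + offset) / denom
    p_down = (np.searchsorted(null, result._logsum_down + eps, side="right") + offset) / denom
    result.p_up = p_up
    result.p_down = p_down
    result.pfp_up = _step_up_pfp(p_up)
    result.pfp_down = _step_up_pfp(p_down)
    result.n_permutations = None if method == "exact" else n_permutations
    result.seed = seed
    return result


def call_degs(
    result: RankProdResult,
    fdr_threshold: float = 0.05,
    contrast: str = "",
    method: str = "rankprod",
) -> DEGSet:
    """Call DEGs at a pfp (false-prediction) threshold.

    Direction is the side with the smaller Rank Product; a gene is called
    if the pfp of that direction is at or below the threshold.
    """
    if result.pfp_up is None:
        raise ValueError("run rankprod_significance first")
    up_side = result.rp_up < result.rp_down
    pfp = np.where(up_side, result.pfp_up, result.pfp_down)
    called = pfp <= fdr_threshold
    genes = [str(g) for g in result.genes[called]]
    direction = {
        str(g): ("up" if u else "down")
        for g, u in zip(result.genes[called], up_side[called])
    }
    return DEGSet(
        contrast=contrast,
        genes=genes,
        direction=direction,
        method=method,
        threshold=fdr_threshold,
        universe=frozenset(str(g) for g in result.genes),
    )


def deg_overlap(deg_sets: list[DEGSet]) -> tuple[dict[str, int], pd.DataFrame]:
    """Venn-region counts and pairwise overlap fractions for >= 2 DEG sets.

    Region keys are '+'/'-' membership strings in input order (e.g. "110").
    The pairwise fraction is |A & B| / min(|A|, |B|).
    """
    if len(deg_sets) < 2:
        raise ValueError("need at least two DEG sets")
    universes = {s.universe for s in deg_sets}
    if len(universes) != 1:
        raise ValueError("DEG sets come from different universes")
    sets = [set(s.genes) for s in deg_sets]
    union = set().union(*sets)
    regions: dict[str, int] = {}
    for mask in itertools.product([1, 0], repeat=len(sets)):
        if not any(mask):
            continue
        region = set(union)
        for m, s in zip(mask, sets):
            region &= s if m else (union - s)
        regions["".join(map(str, mask))] = len(region)
    m = len(sets)
    frac = np.ones((m, m))
    for i in range(m):
        for j in range(m):
            if i != j:
                denom = min(len(sets[i]), len(sets[j]))
                frac[i, j] = len(sets[i] & sets[j]) / denom if denom else 0.0
    labels = [s.contrast or str(i) for i, s in enumerate(deg_sets)]
    return regions, pd.DataFrame(frac, index=labels, columns=labels)


def welch_bh_test(expr_a: pd.DataFrame, expr_b: pd.DataFrame) -> pd.DataFrame:
    """Per-gene Welch t-test with Benjamini-Hochberg adjustment.

    A labeled substitute route for count-model DE (which is out of scope
    here); the Rank Product branch is the primary method.
    """
    if not expr_a.index.equals(expr_b.index):
        raise ValueError("gene indexes must match")
    if expr_a.shape[1] < 2 or expr_b.shape[1] < 2:
        raise ValueError("Welch test needs >= 2 replicates per side")
    res = stats.ttest_ind(
        expr_b.to_numpy(dtype=float),
        expr_a.to_numpy(dtype=float),
        axis=1,
        equal_var=False,
    )
    p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    return pd.DataFrame(
        {
            "log_fc": expr_b.mean(axis=1) - expr_a.mean(axis=1),
            "t": res.statistic,
            "p": p,
            "p_adj": stats.false_discovery_control(p, method="bh"),
        },
        index=expr_a.index,
    )


class RankProductDE(BaseEstimator):
    """sklearn-style wrapper: fit on samples x genes with binary labels.

    Parameters
    ----------
    n_permutations : int
    random_state : int or None
    method : {"permutation", "exact"}
    fdr_threshold : float

    Attributes
    ----------
    result_ : RankProdResult
    degs_ : DEGSet
    """

    def __init__(
        self,
        n_permutations: int = 1000,
        random_state: int | None = None,
        method: str = "permutation",
        fdr_threshold: float = 0.05,
    ):
        self.n_permutations = n_permutations
        self.random_state = random_state
        self.method = method
        self.fdr_threshold = fdr_threshold

    def fit(self, X, y):
        X = pd.DataFrame(X)
        y = np.asarray(y)
        labels = np.unique(y)
        if labels.size != 2:
            raise ValueError("y must contain exactly two classes")
        expr_a = X.loc[y == labels[0]].T  # genes x replicates
        expr_b = X.loc[y == labels[1]].T
        self.result_ = rank_product_stat(expr_a, expr_b)
        rankprod_significance(
            self.result_,
            n_permutations=self.n_permutations,
            seed=self.random_state,
            method=self.method,
        )
        self.degs_ = call_degs(
            self.result_,
            fdr_threshold=self.fdr_threshold,
            contrast=f"{labels[0]}->{labels[1]}",
        )
        return self
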