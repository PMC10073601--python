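"""Over-representation of regulons, gene categories, and modules in gene
sets, by a one-sided binomial test with Bonferroni correction.

For a set of n genes and a category of m genes in a universe of M, the raw
p-value is the upper binomial tail P[X >= x] with X ~ Bin(n, m/M) and x
observed members.  Categories are filtered by size before testing (regulons
with at least 11 members, gene categories with at least 31, configurable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FunctionMap",
    "filter_categories",
    "binomial_enrichment",
    "module_deg_enrichment",
]

#: size filters: "more than 10 regulatees" / "more than 30 genes", strict
MIN_REGULON_SIZE = 11
MIN_CATEGORY_SIZE = 31


@dataclass
class FunctionMap:
    """Categories (regulons / gene categories / modules) and their members."""

    members: dict[str, set]  # category id -> gene ids
    kind: str = "regulon"  # "regulon" | "gene_category" | "module"

    @classmethod
    def from_table(cls, table: pd.DataFrame, kind: str = "regulon") -> "FunctionMap":
        """Build from a 2-column (category_id, gene_id) table."""
        members: dict[str, set] = {}
        for cat, gene in zip(table.iloc[:, 0], table.iloc[:, 1]):
            members.setdefault(str(cat), set()).add(str(gene))
        return cls(members=members, kind=kind)


def filter_categories(
    fmap: FunctionMap,
    universe: set,
    min_regulon: int = MIN_REGULON_SIZE,
    min_category: int = MIN_CATEGORY_SIZE,
) -> FunctionMap:
    """Intersect categories with the universe, then apply the size filter.

    Regulons keep >= ``min_regulon`` members, other kinds >= ``min_category``.
    """
    min_size = min_regulon if fmap.kind == "regulon" else min_category
    kept = {}
    for cat, genes in fmap.members.items():
        g = genes & universe
        if len(g) >= min_size:
            kept[cat] = g
    if not kept:
        raise ValueError("no category survives the size filter")
    return FunctionMap(members=kept, kind=fmap.kind)


def binomial_enrichment(
    gene_set: set,
    fmap: FunctionMap,
    universe: set,
    alpha: float = 0.05,
    n_tests: int | None = None,
) -> pd.DataFrame:
    """One-sided binomial over-representation test per category.

    Returns a table with observed count x, set size n, category size m,
    universe size M, raw p, Bonferroni p (over ``n_tests`` categories,
    default the number tested here), and a significance flag.
    """
    gene_set = set(gene_set) & universe
    M = len(universe)
    n = len(gene_set)
    if M == 0:
        raise ValueError("empty universe")
    rows = []
    names = []
    for cat, genes in sorted(fmap.members.items()):
        g = genes & universe
        m = len(g)
        if m == 0:
            warnings.warn(f"category {cat} empty after universe intersection")
            continue
        x = len(gene_set & g)
        p = float(stats.binom.sf(x - 1, n, m / M)) if n > 0 else 1.0
        rows.append((x, n, m, M, p))
        names.append(cat)
    if not rows:
        raise ValueError("no testable category")
    table = pd.DataFrame(
        rows, index=names, columns=["x", "n", "m", "M", "p"]
    )
    k = n_tests if n_tests is not None else len(table)
    table["p_bonferroni"] = np.minimum(table["p"] * k, 1.0)
    table["significant"] = table["p_bonferroni"] <= alpha
    return table


def module_deg_enrichment(
    modules: dict[str, set],
    deg_sets: dict[str, set],
    universe: set,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Binomial enrichment of every DEG set in every module.

    Bonferroni correction spans modules x contrasts.  Returns a long table
    indexed by (module, contrast).
    """
    fmap = FunctionMap(members=modules, kind="module")
    n_tests = sum(
        1
        for genes in modules.values()
        if len(genes & universe) > 0
    ) * len(deg_sets)
    frames = []
    for contrast, degs in deg_sets.items():
        t = binomial_enrichment(degs, fmap, universe, alpha=alpha, n_tests=n_tests)
        t["contrast"] = contrast
        t["module"] = t.index
        frames.append(t)
    out = pd.concat(frames, ignore_index=True)
    return out.set_index(["module", "contrast"])
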