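"""Transcriptome epistasis: regression of the simultaneous change under two
perturbations on the sum of the single-perturbation changes.

The per-gene change Delta between two conditions is the difference of
replicate-mean log expression.  The slope alpha of the through-origin
least-squares regression  simultaneous = alpha * (single1 + single2)
classifies the interaction: alpha = 1 additivity, alpha < 1 negative
epistasis (the perturbations cancel), alpha > 1 positive epistasis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "DeltaProfile",
    "EpistasisResult",
    "delta_profile",
    "epistasis_slope",
    "classify_epistasis",
    "EpistasisRegressor",
]


@dataclass
class DeltaProfile:
    """Per-gene log-expression change between two condition means."""

    values: pd.Series  # indexed by gene id
    contrast: str = ""  # e.g. "dGS"
    cond_from: str = ""
    cond_to: str = ""


@dataclass
class EpistasisResult:
    alpha: float
    n_genes: int
    classification: str
    residual_ss: float
    total_ss: float


def delta_profile(
    expr: pd.DataFrame,
    design: pd.DataFrame,
    cond_from: str,
    cond_to: str,
    contrast: str = "",
) -> DeltaProfile:
    """Difference of replicate-mean log expression, cond_to - cond_from.

    ``design`` must have a ``condition`` column indexed by sample name
    (matching ``expr`` columns).
    """
    values = {}
    for cond in (cond_from, cond_to):
        samples = design.index[design["condition"] == cond]
        samples = [s for s in samples if s in expr.columns]
        if not samples:
            raise ValueError(f"condition not present in expression data: {cond}")
        values[cond] = expr[samples].mean(axis=1)
    return DeltaProfile(
        values=values[cond_to] - values[cond_from],
        contrast=contrast or f"{cond_from}->{cond_to}",
        cond_from=cond_from,
        cond_to=cond_to,
    )


class EpistasisRegressor(BaseEstimator, RegressorMixin):
    """Through-origin least-squares regression y = alpha * x.

    Matches the interceptless epistasis model; an intercept mode is
    available for sensitivity analysis (``fit_intercept=True``) but is not
    the default.

    Parameters
    ----------
    fit_intercept : bool
        If True, fit y = alpha * x + b instead.
    tolerance : float
        Half-width of the additivity band used by :meth:`classify`.

    Attributes
    ----------
    alpha_ : float
        Fitted slope (``coef_`` alias provided for sklearn conventions).
    intercept_ : float
        0.0 in the default through-origin mode.
    classification_ : str
        "additive", "positive", or "negative".
    """

    def __init__(self, fit_intercept: bool = False, tolerance: float = 0.05):
        self.fit_intercept = fit_intercept
        self.tolerance = tolerance

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.size != y.size:
            raise ValueError("x and y must align")
        if x.size < 3:
            raise ValueError("need at least three genes")
        if self.fit_intercept:
            xc, yc = x - x.mean(), y - y.mean()
            denom = float(xc @ xc)
            if denom == 0.0:
                raise ValueError("slope undefined: x has no variation")
            self.alpha_ = float(xc @ yc) / denom
            self.intercept_ = float(y.mean() - self.alpha_ * x.mean())
        else:
            denom = float(x @ x)
            if denom == 0.0:
                raise ValueError("slope undefined: x identically zero")
            self.alpha_ = float(x @ y) / denom
            self.intercept_ = 0.0
        self.coef_ = np.array([self.alpha_])
        resid = y - self.predict(x)
        self.residual_ss_ = float(resid @ resid)
        self.total_ss_ = float(y @ y)
        self.n_genes_ = int(x.size)
        self.classification_ = classify_epistasis(self.alpha_, self.tolerance)
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).reshape(-1)
        return self.alpha_ * x + self.intercept_


def epistasis_slope(
    simultaneous: DeltaProfile,
    single_a: DeltaProfile,
    single_b: DeltaProfile,
    tolerance: float = 0.05,
    fit_intercept: bool = False,
) -> EpistasisResult:
    """Slope of simultaneous change regressed on the additive change.

    x = single_a + single_b (aligned on the shared gene set), y = the
    simultaneous profile; through-origin alpha = sum(x*y) / sum(x^2).
    """
    genes = simultaneous.values.index
    genes = genes.intersection(single_a.values.index).intersection(
        single_b.values.index
    )
    if len(genes) < 3:
        raise ValueError("need at least three shared genes")
    x = (single_a.values.loc[genes] + single_b.values.loc[genes]).to_numpy()
    y = simultaneous.values.loc[genes].to_numpy()
    reg = EpistasisRegressor(fit_intercept=fit_intercept, tolerance=tolerance).fit(x, y)
    return EpistasisResult(
        alpha=reg.alpha_,
        n_genes=reg.n_genes_,
        classification=reg.classification_,
        residual_ss=reg.residual_ss_,
        total_ss=reg.total_ss_,
    )


def classify_epistasis(alpha: float, tolerance: float = 0.05) -> str:
    """Classify an epistasis slope against the additivity reference of 1."""
    if not np.isfinite(alpha):
        raise ValueError("alpha must be finite")
    if abs(alpha - 1.0) <= tolerance:
        return "additive"
    return "positive" if alpha > 1.0 else "negative"
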