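"""Growth-rate extraction from OD600 time series.

The growth rate of a well is the mean of the three consecutive pointwise
rates mu_i = ln(C_{i+1}/C_i) / (t_{i+1}-t_i) whose window has the largest
mean; among near-tied windows the one with the smallest variance wins.
Growth fitness of a condition is the mean rate over biological replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GrowthCurve",
    "GrowthRateResult",
    "pointwise_rates",
    "select_growth_rate",
    "growth_fitness",
    "dose_response_pick",
    "welch_compare",
]

#: windows whose mean is within this relative margin of the best mean
#: compete on variance instead of mean
MEAN_TIE_RTOL = 0.01


@dataclass
class GrowthCurve:
    """One well's OD600 trajectory.

    Parameters
    ----------
    times : array-like of float
        Sampling times in hours, strictly increasing.
    od : array-like of float
        OD600 readings, strictly positive.
    label : str, optional
        Free-form well/strain/condition label.
    """

    times: np.ndarray
    od: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.shape != self.od.shape:
            raise ValueError("times and od must have the same length")


@dataclass
class GrowthRateResult:
    """Windowed growth-rate estimate for one curve."""

    mu: float
    window_start_index: int
    window_mu_values: np.ndarray = field(repr=False)
    window_variance: float = 0.0


def pointwise_rates(curve: GrowthCurve) -> np.ndarray:
    """Per-interval exponential rates mu_i = ln(C_{i+1}/C_i)/(t_{i+1}-t_i)."""
    t, c = curve.times, curve.od
    if t.size < 2:
        raise ValueError("need at least two time points")
    bad = np.flatnonzero(c <= 0)
    if bad.size:
        raise ValueError(f"non-positive OD at index {bad[0]}")
    dt = np.diff(t)
    if np.any(dt <= 0):
        idx = int(np.flatnonzero(dt <= 0)[0])
        raise ValueError(f"times not strictly increasing at index {idx}")
    return np.diff(np.log(c)) / dt


def _window_stats(rates: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Means and (population) variances of all 3-point windows."""
    w = np.lib.stride_tricks.sliding_window_view(rates, 3)
    return w.mean(axis=1), w.var(axis=1)


def select_growth_rate(rates: Sequence[float]) -> GrowthRateResult:
    """Pick the steady exponential-phase window of three consecutive rates.

    Primary criterion: largest window mean.  Windows whose mean is within a
    noise-scaled margin of the maximum — the larger of 1% (relative) and the
    typical within-window rate scatter (median window SD) — compete on
    smallest variance; remaining ties resolve to the earliest window.  The
    noise-scaled margin keeps the selection from chasing upward noise
    excursions when the exponential phase spans many windows.
    """
    rates = np.asarray(rates, dtype=float)
    if rates.size < 3:
        raise ValueError("need at least three pointwise rates")
    means, variances = _window_stats(rates)
    best_mean = means.max()
    noise_scale = float(np.median(np.sqrt(variances)))
    margin = max(MEAN_TIE_RTOL * abs(best_mean), noise_scale)
    candidates = np.flatnonzero(means >= best_mean - margin)
    # among near-tied means, smallest variance; argmin takes the earliest tie
    start = int(candidates[np.argmin(variances[candidates])])
    return GrowthRateResult(
        mu=float(means[start]),
        window_start_index=start,
        window_mu_values=rates[start : start + 3].copy(),
        window_variance=float(variances[start]),
    )


def growth_fitness(curves: Sequence[GrowthCurve]) -> float:
    """Mean growth rate over biological replicates (the growth fitness)."""
    if len(curves) == 0:
        raise ValueError("empty replicate set")
    mus = [select_growth_rate(pointwise_rates(c)).mu for c in curves]
    return float(np.mean(mus))


def dose_response_pick(
    concentrations: Sequence[float],
    rates: Sequence[float],
    target_fraction: float = 0.30,
) -> tuple[float, float]:
    """Pick the stressor concentration reducing growth by ``target_fraction``.

    Returns ``(picked, refined)``: the smallest *tested* concentration whose
    relative rate decrease from the zero-concentration reference reaches the
    target, and a linearly interpolated refinement between the bracketing
    pair of tested points.
    """
    conc = np.asarray(concentrations, dtype=float)
    rate = np.asarray(rates, dtype=float)
    order = np.argsort(conc)
    conc, rate = conc[order], rate[order]
    if conc[0] != 0:
        raise ValueError("rate at concentration 0 is required as reference")
    if target_fraction <= 0:
        return float(conc[0]), float(conc[0])
    r0 = rate[0]
    threshold = (1.0 - target_fraction) * r0
    reached = np.flatnonzero(rate <= threshold)
    if reached.size == 0:
        max_dec = float(1.0 - rate.min() / r0)
        raise ValueError(
            f"target decrease {target_fraction:.0%} never reached "
            f"(max observed decrease {max_dec:.1%})"
        )
    i = int(reached[0])
    picked = float(conc[i])
    if i == 0:
        return picked, picked
    lo, hi = rate[i - 1], rate[i]
    if lo == hi:
        refined = picked
    else:
        frac = (lo - threshold) / (lo - hi)
        refined = float(conc[i - 1] + frac * (conc[i] - conc[i - 1]))
    return picked, refined


def welch_compare(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Two-sided Welch t-test p-value between two groups of growth rates."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        # degenerate: no within-group variability
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)
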