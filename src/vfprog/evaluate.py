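"""Comparison framework for progression tests.

Positive-rate curves over a significance grid, false-positive-rate curves
obtained by randomly re-ordering each series in time (which reduces any
systematic change to chance while preserving marginal properties), and
specificity-equated comparison: plotting/reading positive rates at matched
*empirical* false-positive rates rather than matched nominal alpha, so a
method with a miscalibrated p-value is not credited for its extra
positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import VFSeries
from .simulate import reorder_in_time

__all__ = [
    "EvalCurves",
    "default_alpha_grid",
    "positive_rate_curve",
    "fpr_curve",
    "equate_specificity",
    "paired_difference_ci",
]


def default_alpha_grid(n: int = 60) -> np.ndarray:
    """Log-spaced significance grid over [0.001, 0.15], endpoints included."""
    return np.logspace(np.log10(0.001), np.log10(0.15), n)


@dataclass
class EvalCurves:
    """Per-method positive/false-positive rates over a significance grid."""

    alpha_grid: np.ndarray
    positive_rate: np.ndarray | None = None
    false_positive_rate: np.ndarray | None = None
    n_series: int = 0
    n_excluded: int = 0
    extras: dict = field(default_factory=dict)


def positive_rate_curve(p_values, alpha_grid) -> np.ndarray:
    """Proportion of series with p strictly below each alpha."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values supplied")
    alpha = np.asarray(alpha_grid, dtype=float)
    return np.mean(p[:, None] < alpha[None, :], axis=0)


def fpr_curve(cohort, runner, alpha_grid, seed, n_repeats: int = 1) -> EvalCurves:
    """False-positive-rate curve from random temporal re-ordering of each series.

    By default each series is re-ordered once (the economical published
    procedure); ``n_repeats > 1`` pools several independent re-orderings
    per series for a tighter estimate.  ``runner(series)`` must return an
    object with ``p_global`` and ``status`` (a
    :class:`~vfprog.model.ProgressionResult`).  Re-ordered series whose fit
    fails are excluded from the rates and counted in ``n_excluded``.
    """
    cohort = list(cohort)
    if not cohort:
        raise ValueError("empty cohort")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    rng = np.random.default_rng(seed)
    p_vals = []
    n_excluded = 0
    for s in cohort:
        for _ in range(n_repeats):
            shuffled = reorder_in_time(s, rng)
            res = runner(shuffled)
            if res.status == "ok":
                p_vals.append(res.p_global)
            else:
                n_excluded += 1
    if not p_vals:
        raise ValueError("every series failed; no false-positive rate available")
    alpha = np.asarray(alpha_grid, dtype=float)
    return EvalCurves(
        alpha_grid=alpha,
        false_positive_rate=positive_rate_curve(p_vals, alpha),
        n_series=len(cohort),
        n_excluded=n_excluded,
    )


def equate_specificity(curves_pr: EvalCurves, curves_fpr: EvalCurves, fpr_query):
    """Positive rate at requested empirical false-positive rates.

    Pairs (FPR(alpha), PR(alpha)) over the shared alpha grid and reads PR
    at the queried FPR values by monotone linear interpolation.  Queries
    outside the observed FPR range return the boundary PR and are flagged.

    Returns ``(pr_at_fpr, extrapolated)`` arrays.
    """
    if not np.array_equal(curves_pr.alpha_grid, curves_fpr.alpha_grid):
        raise ValueError("curves must share the same alpha grid")
    fpr = np.asarray(curves_fpr.false_positive_rate, dtype=float)
    pr = np.asarray(curves_pr.positive_rate, dtype=float)
    q = np.atleast_1d(np.asarray(fpr_query, dtype=float))
    order = np.argsort(fpr, kind="stable")
    fpr_s, pr_s = fpr[order], pr[order]
    out = np.interp(q, fpr_s, pr_s)
    extrapolated = (q < fpr_s[0]) | (q > fpr_s[-1])
    return out, extrapolated


def paired_difference_ci(
    p_a, p_b, alpha: float, n_boot: int = 2000, seed=None
) -> tuple[float, float, float]:
    """Difference of positive rates at a common threshold, with bootstrap CI.

    ``p_a`` and ``p_b`` are global p-values of two methods over the *same*
    series, in the same order; ``alpha`` is the (possibly
    specificity-equated) threshold applied to both.  Returns
    ``(difference, lo, hi)`` where difference = rate(a) - rate(b), with a
    paired percentile bootstrap over series (95% CI).
    """
    p_a = np.asarray(p_a, dtype=float)
    p_b = np.asarray(p_b, dtype=float)
    if p_a.shape != p_b.shape:
        raise ValueError("p_a and p_b must have equal length (paired series)")
    n = len(p_a)
    diff = float(np.mean(p_a < alpha) - np.mean(p_b < alpha))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot = np.mean(p_a[idx] < alpha, axis=1) - np.mean(p_b[idx] < alpha, axis=1)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return diff, float(lo), float(hi)
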