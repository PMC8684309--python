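"""ANSWERS: non-stationary Weibull error regression with spatial enhancement.

The method shares PoPLR's skeleton — 52 local p-values for deterioration,
combined as S = -sum(ln p) (the statistic usually written I-minus) — but
replaces least squares with per-location maximum likelihood under the
sensitivity-dependent reflected-Weibull error model of
:mod:`vfprog.errors`, enhances local evidence across nerve-fiber-bundle
sectors, and, in its original form, converts S to a p-value with cutoffs
from a *reference population* rather than the individual series.

Three variants are provided:

- ``answers``  : spatial enhancement on, population p-values
  (:func:`population_p` against a reference pool of null S values);
- ``answer``   : identical but with the identity spatial-weight matrix
  (no enhancement); its reference pool must be generated separately;
- ``answers_perm`` ("modified" form): the ANSWERS statistic with an
  individualized permutation p-value, as in PoPLR
  (:func:`answers_permutation_p`).

Each series involves 104 free parameters (intercept and slope at each of
the 52 locations), optimized as 52 independent two-parameter problems by a
derivative-free simplex search run in parallel across locations.  The
optimizer can fail to converge, or the observed-information standard
errors can be unusable, on some (especially permuted) series; failures are
reported, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ErrorModelTable
from .model import N_LOC, ProgressionResult, VFSeries
from .poplr import P_MIN, fit_pointwise, s_statistic

__all__ = [
    "SpatialWeights",
    "AnswersFit",
    "fit_answers",
    "spatial_enhance",
    "answers_statistic",
    "population_p",
    "answers_permutation_p",
    "run_answers",
    "build_reference_pool",
]


# ---------------------------------------------------------------------------
# spatial weights
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpatialWeights:
    """Row-stochastic 52 x 52 non-negative weight matrix.

    Local evidence is pooled as a weighted average of log p-values over
    neighbours; the identity matrix disables enhancement (ANSWER mode).
    """

    W: np.ndarray

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        object.__setattr__(self, "W", W)
        if W.shape != (N_LOC, N_LOC):
            raise ValueError(f"W must be {N_LOC}x{N_LOC}")
        if np.any(W < 0):
            raise ValueError("weights must be non-negative")
        if not np.allclose(W.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("rows of W must sum to 1")

    @classmethod
    def identity(cls) -> "SpatialWeights":
        return cls(np.eye(N_LOC))

    @classmethod
    def sector_uniform(cls, grid) -> "SpatialWeights":
        """Uniform weights within each nerve-fiber-bundle sector.

        The simplest row-stochastic kernel consistent with bundle anatomy:
        every location pools equally over its sector mates (itself
        included) and not at all across sectors.
        """
        W = np.zeros((N_LOC, N_LOC))
        for s in np.unique(grid.sector):
            m = grid.sector == s
            W[np.ix_(m, m)] = 1.0 / m.sum()
        return cls(W)

    @property
    def is_identity(self) -> bool:
        return bool(np.array_equal(self.W, np.eye(N_LOC)))


def spatial_enhance(p_local_raw, weights: SpatialWeights) -> np.ndarray:
    """Pool log p-values over sector neighbours: ln p~ = W ln p.

    With the identity matrix the output equals the input exactly (ANSWER
    mode).  Inputs are clamped to [P_MIN, 1] first.
    """
    p = np.clip(np.asarray(p_local_raw, dtype=float), P_MIN, 1.0)
    if weights.is_identity:
        return p
    return np.exp(weights.W @ np.log(p))


def answers_statistic(p_enhanced) -> float:
    """Combined statistic I-minus: identical to the PoPLR S-statistic."""
    return s_statistic(p_enhanced)


# ---------------------------------------------------------------------------
# per-location ML fit (batched over locations)
# ---------------------------------------------------------------------------

@dataclass
class AnswersFit:
    """Maximum-likelihood fit of one series (104 free parameters).

    ``loc_ok`` flags locations whose optimizer converged with a usable
    (finite, positive) slope standard error; ``status`` is "failed" as
    soon as any location is unusable, because the combined statistic
    needs all 52 local p-values.
    """

    intercepts: np.ndarray
    slopes: np.ndarray
    se_slopes: np.ndarray
    loglik: float
    p_local_raw: np.ndarray
    loc_ok: np.ndarray
    status: str = "ok"
    p_local_enhanced: np.ndarray | None = field(default=None)

    @property
    def n_free_parameters(self) -> int:
        return 2 * len(self.slopes)


def _neg_loglik_factory(times: np.ndarray, Y: np.ndarray, table: ErrorModelTable):
    """Batched negative log-likelihood for 52 independent (a, b) problems.

    Returns f(params) with params shaped (L, K, 2) -> (L, K).  Observations
    at the 0 dB floor contribute a left-censored term log P(error <= -mu);
    the linear predictor is clamped to [0, 40] for the error-bin lookup so
    the lookup is always defined.
    """
    YT = Y.T  # (L, T)
    cens_all = YT <= 0.0
    edges, kk, lam, cc = table.edges, table.shape, table.scale, table.shift

    def f(params: np.ndarray, rows=slice(None)) -> np.ndarray:
        Yr = YT[rows]
        cens = cens_all[rows]
        a = params[..., 0:1]  # (L, K, 1)
        b = params[..., 1:2]
        pred = a + b * times  # (L, K, T)
        level = np.clip(pred, 0.0, 40.0)
        bi = np.clip(np.searchsorted(edges, level, side="right") - 1, 0, len(kk) - 1)
        k_b, l_b, c_b = kk[bi], lam[bi], cc[bi]
        u = c_b - (Yr[:, None, :] - pred)
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            obs = np.where(
                u > 0,
                np.log(k_b / l_b) + (k_b - 1.0) * np.log(u / l_b) - (u / l_b) ** k_b,
                -np.inf,
            )
            # left-censored at the floor: error <= 0 - pred
            w = c_b + pred
            cns = np.where(w > 0, -((np.maximum(w, 0.0) / l_b) ** k_b), 0.0)
        ll = np.where(cens[:, None, :], cns, obs)
        return -np.sum(ll, axis=-1)

    return f


def _nelder_mead_batch(f, x0, steps, max_iter=400, fatol=1e-7, xatol=1e-5):
    """Nelder-Mead on L independent 2-parameter problems simultaneously.

    Standard coefficients (reflection 1, expansion 2, contraction 0.5,
    shrink 0.5), vectorized with per-problem masks.  Returns (x, fval,
    converged).
    """
    L, n = x0.shape
    sim = np.repeat(x0[:, None, :], n + 1, axis=1)  # (L, 3, 2)
    for j in range(n):
        sim[:, j + 1, j] += steps[j]
    fv = f(sim)
    converged = np.zeros(L, dtype=bool)

    for _ in range(max_iter):
        order = np.argsort(fv, axis=1)
        sim = np.take_along_axis(sim, order[..., None], axis=1)
        fv = np.take_along_axis(fv, order, axis=1)

        fspread = fv[:, -1] - fv[:, 0]
        xspread = np.max(np.abs(sim - sim[:, :1, :]), axis=(1, 2))
        converged = np.isfinite(fv[:, 0]) & (fspread < fatol) & (xspread < xatol)
        if converged.all():
            break

        centroid = sim[:, :n, :].mean(axis=1)
        worst = sim[:, -1, :]
        xr = centroid + (centroid - worst)
        xe = centroid + 2.0 * (centroid - worst)
        xoc = centroid + 0.5 * (centroid - worst)
        xic = centroid - 0.5 * (centroid - worst)
        cand = np.stack([xr, xe, xoc, xic], axis=1)  # (L, 4, 2)
        fc = f(cand)
        fr, fe, foc, fic = fc[:, 0], fc[:, 1], fc[:, 2], fc[:, 3]
        f0, f1, fw = fv[:, 0], fv[:, -2], fv[:, -1]

        new_x = worst.copy()
        new_f = fw.copy()
        shrink = np.zeros(L, dtype=bool)

        m = fr < f0  # expand
        take_e = m & (fe < fr)
        new_x = np.where(take_e[:, None], xe, np.where(m[:, None], xr, new_x))
        new_f = np.where(take_e, fe, np.where(m, fr, new_f))

        m2 = (~m) & (fr < f1)  # accept reflection
        new_x = np.where(m2[:, None], xr, new_x)
        new_f = np.where(m2, fr, new_f)

        m3 = (~m) & (~m2) & (fr < fw)  # outside contraction
        ok3 = m3 & (foc <= fr)
        new_x = np.where(ok3[:, None], xoc, new_x)
        new_f = np.where(ok3, foc, new_f)
        shrink |= m3 & ~ok3

        m4 = (~m) & (~m2) & (~m3)  # inside contraction
        ok4 = m4 & (fic < fw)
        new_x = np.where(ok4[:, None], xic, new_x)
        new_f = np.where(ok4, fic, new_f)
        shrink |= m4 & ~ok4

        active = ~converged
        upd = active & ~shrink
        sim[upd, -1, :] = new_x[upd]
        fv[upd, -1] = new_f[upd]

        sh = shrink & active
        if np.any(sh):
            sim[sh] = sim[sh, :1, :] + 0.5 * (sim[sh] - sim[sh, :1, :])
            fv[sh] = f(sim)[sh]

    order = np.argsort(fv, axis=1)
    sim = np.take_along_axis(sim, order[..., None], axis=1)
    fv = np.take_along_axis(fv, order, axis=1)
    return sim[:, 0, :], fv[:, 0], converged


def _hessian_batch(f, x, h=(1e-4, 1e-5)):
    """Central-difference 2x2 Hessians for L problems; f as in the NM batch."""
    L = x.shape[0]
    ha, hb = h
    e0 = np.array([ha, 0.0])
    e1 = np.array([0.0, hb])
    pts = np.stack(
        [
            x,
            x + e0, x - e0, x + e1, x - e1,
            x + e0 + e1, x + e0 - e1, x - e0 + e1, x - e0 - e1,
        ],
        axis=1,
    )  # (L, 9, 2)
    fv = f(pts)
    with np.errstate(invalid="ignore"):
        f00 = fv[:, 0]
        daa = (fv[:, 1] - 2 * f00 + fv[:, 2]) / ha**2
        dbb = (fv[:, 3] - 2 * f00 + fv[:, 4]) / hb**2
        dab = (fv[:, 5] - fv[:, 6] - fv[:, 7] + fv[:, 8]) / (4 * ha * hb)
    H = np.empty((L, 2, 2))
    H[:, 0, 0] = daa
    H[:, 1, 1] = dbb
    H[:, 0, 1] = H[:, 1, 0] = dab
    return H


def _feasible_start(times, Y, table, slopes0, intercepts0):
    """Nudge OLS starting intercepts up until every residual is below the
    support bound, so the simplex starts at finite log-likelihood."""
    c_min = float(table.shift.min())
    a_req = (Y - np.outer(times, slopes0)).max(axis=0) - c_min + 0.05
    return np.maximum(intercepts0, a_req)


def _scan_start(f, a_center, b_center, a_feas):
    """Coarse (a, b) scan per location; returns the best node as a start.

    The binned likelihood is multimodal (distinct basins correspond to
    different slope readings of the same noisy trajectory), so a local
    search needs a basin-aware start.  A 33 x 31 grid spanning +/-4 dB and
    +/-1.5 dB/year around the OLS fit (plus the guaranteed-feasible node)
    is evaluated in one vectorized call; the steps (0.25 dB, 0.1 dB/year)
    are small enough to land inside the narrow high-sensitivity basins.
    """
    L = len(a_center)
    a_off = np.linspace(-4.0, 4.0, 33)
    b_off = np.linspace(-1.5, 1.5, 31)
    na, nb = len(a_off), len(b_off)
    A = a_center[:, None, None] + a_off[None, :, None]
    B = b_center[:, None, None] + b_off[None, None, :]
    cand = np.stack(
        [np.broadcast_to(A, (L, na, nb)), np.broadcast_to(B, (L, na, nb))],
        axis=-1,
    ).reshape(L, na * nb, 2)
    feas = np.stack([a_feas, b_center], axis=1)[:, None, :]
    cand = np.concatenate([cand, feas], axis=1)
    fv = f(cand)
    fv = np.where(np.isfinite(fv), fv, np.inf)
    best = np.argmin(fv, axis=1)
    return cand[np.arange(L), best]


def fit_answers(series: VFSeries, table: ErrorModelTable) -> AnswersFit:
    """Per-location ML regression under the Weibull error model.

    Each location's (intercept, slope) maximizes the summed log-density of
    residuals y_t - (a + b t), with 0 dB observations entering as
    left-censored terms.  Standard errors come from the numerically
    observed information; the raw local p-value is the one-sided Wald
    p = Phi(slope / se), clamped to [P_MIN, 1].

    The likelihood is piecewise in the linear predictor (binned error
    parameters), so local optima occur, typically where a trajectory
    straddles a bin boundary.  The search therefore runs from two starts —
    the OLS fit and the best node of a coarse (a, b) scan — in one stacked
    batch and keeps the better optimum per location; non-converged
    locations are retried once from a perturbed start before being
    declared failed.  A
    fit is ``status == "failed"`` if any location fails — mirroring the
    reported behaviour of the method on real and permuted series.
    """
    if series.n_visits < 3:
        raise ValueError("ANSWERS regression needs at least 3 visits")
    times, Y = series.times, series.values
    L = Y.shape[1]
    f = _neg_loglik_factory(times, Y, table)

    ols = fit_pointwise(series)
    a_ols = _feasible_start(times, Y, table, ols.slope, ols.intercept)
    x0 = np.stack([a_ols, ols.slope], axis=1)  # (L, 2)
    x_scan = _scan_start(f, ols.intercept, ols.slope, a_ols)
    x0_stacked = np.concatenate([x0, x_scan])
    rows = np.concatenate([np.arange(L), np.arange(L)])
    f_stacked = lambda p: f(p, rows=rows)
    x2, fval2, conv2 = _nelder_mead_batch(f_stacked, x0_stacked, steps=(1.0, 0.25))
    pick = np.where(fval2[:L] <= fval2[L:], np.arange(L), np.arange(L, 2 * L))
    x, fval, conv = x2[pick], fval2[pick], conv2[pick]

    retry = ~conv | ~np.isfinite(fval)
    if np.any(retry):
        idx = np.flatnonzero(retry)
        f_sub = lambda p: f(p, rows=idx)
        x1 = x0[idx] + np.array([2.0, -0.1])
        xr, fr, cr = _nelder_mead_batch(f_sub, x1, steps=(0.5, 0.1))
        better = fr < fval[idx]
        x[idx[better]] = xr[better]
        fval[idx[better]] = fr[better]
        conv[idx] = conv[idx] | cr

    H = _hessian_batch(f, x)
    det = H[:, 0, 0] * H[:, 1, 1] - H[:, 0, 1] ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        var_b = H[:, 0, 0] / det
        se = np.sqrt(var_b)
    usable = (
        conv
        & np.isfinite(fval)
        & np.isfinite(se)
        & (se > 0)
        & (det > 0)
        & (H[:, 0, 0] > 0)
    )
    with np.errstate(invalid="ignore"):
        p_raw = np.clip(stats.norm.cdf(x[:, 1] / se), P_MIN, 1.0)
    p_raw = np.where(usable, p_raw, np.nan)

    return AnswersFit(
        intercepts=x[:, 0],
        slopes=x[:, 1],
        se_slopes=se,
        loglik=float(-np.sum(fval)),
        p_local_raw=p_raw,
        loc_ok=usable,
        status="ok" if usable.all() else "failed",
    )


# ---------------------------------------------------------------------------
# global p-values
# ---------------------------------------------------------------------------

def run_answers(
    series: VFSeries,
    table: ErrorModelTable,
    weights: SpatialWeights,
    null_S=None,
) -> ProgressionResult:
    """Fit, enhance, combine; population p-value if a reference pool is given.

    Returns a :class:`ProgressionResult` with method "answers" (or
    "answer" when ``weights`` is the identity).  ``p_global`` is NaN when
    ``null_S`` is None or the fit failed.
    """
    method = "answer" if weights.is_identity else "answers"
    fit = fit_answers(series, table)
    if fit.status != "ok":
        return ProgressionResult(
            series.series_id, method, np.nan, np.nan,
            fit.slopes, np.full(N_LOC, np.nan), "failed",
            extras={"n_loc_failed": int((~fit.loc_ok).sum())},
        )
    p_enh = spatial_enhance(fit.p_local_raw, weights)
    fit.p_local_enhanced = p_enh
    S = answers_statistic(p_enh)
    p_global = population_p(S, null_S) if null_S is not None else np.nan
    return ProgressionResult(
        series.series_id, method, S, p_global, fit.slopes, p_enh, "ok"
    )


def population_p(S_obs: float, null_S) -> float:
    """Population-cutoff p-value: p = (1 + #{null >= S_obs}) / (N + 1).

    ``null_S`` is a pool of S values from a reference group of stable
    series (method-specific: pools for the spatially enhanced and the
    plain variant must be generated separately).
    """
    null_S = np.asarray(null_S, dtype=float)
    if null_S.size == 0:
        raise ValueError("reference pool must be non-empty")
    return float((1 + np.sum(null_S >= S_obs)) / (null_S.size + 1))


def build_reference_pool(
    cohort, table: ErrorModelTable, weights: SpatialWeights
) -> np.ndarray:
    """S values of a reference cohort (failed fits dropped, as unusable)."""
    out = []
    for s in cohort:
        r = run_answers(s, table, weights)
        if r.ok:
            out.append(r.S)
    if not out:
        raise ValueError("no reference series could be fitted")
    return np.asarray(out)


def answers_permutation_p(
    series: VFSeries,
    table: ErrorModelTable,
    weights: SpatialWeights,
    n_perm: int = 1000,
    seed=None,
    strict: bool = False,
) -> ProgressionResult:
    """Individualized ("modified ANSWERS") p-value by permutation.

    The ANSWERS statistic of the observed series is compared with its
    value over ``n_perm`` random re-orderings of the visits.  Permutations
    whose fit fails are excluded from the denominator; their count is
    reported in ``extras['n_perm_failed']``.  If the observed fit fails,
    the result is status "failed" with an undefined p-value.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    obs = run_answers(series, table, weights)
    if not obs.ok:
        obs.method = "answers_perm"
        return obs

    s_perm = []
    n_failed = 0
    for _ in range(n_perm):
        perm = rng.permutation(series.n_visits)
        shuffled = VFSeries(
            series.series_id, series.eye, series.times, series.values[perm]
        )
        r = run_answers(shuffled, table, weights)
        if r.ok:
            s_perm.append(r.S)
        else:
            n_failed += 1
    n_eff = len(s_perm)
    if n_eff == 0:
        return ProgressionResult(
            series.series_id, "answers_perm", obs.S, np.nan,
            obs.slopes, obs.p_local, "failed",
            extras={"n_perm_failed": n_failed, "n_perm_used": 0},
        )
    s_perm = np.asarray(s_perm)
    hits = int(np.sum(s_perm > obs.S if strict else s_perm >= obs.S))
    return ProgressionResult(
        series.series_id, "answers_perm", obs.S, hits / n_eff,
        obs.slopes, obs.p_local, "ok",
        extras={"n_perm_failed": n_failed, "n_perm_used": n_eff},
    )
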