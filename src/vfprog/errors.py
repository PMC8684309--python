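"""Sensitivity-dependent (non-stationary) Weibull model of threshold errors.

Perimetric test-retest errors are skewed and heteroscedastic: retest
variability grows as sensitivity falls (deeper defect), and large negative
excursions are far more common than large positive ones.  This module models
the measurement error at a location with true sensitivity ``level`` as a
*reflected, shifted* Weibull variate

    error = c - W,   W ~ Weibull(shape=k, scale=lam),

with (k, lam) looked up in a sensitivity bin of ``level`` and the shift
``c = lam * Gamma(1 + 1/k)`` chosen so the error has mean exactly zero.  The
error support is (-inf, c]: bounded above, long left tail.

The same family serves two roles: the likelihood of the ANSWERS regression
(:mod:`vfprog.answers`) and the "weibull" noise mode of the synthetic
generator (:mod:`vfprog.simulate`), so well-specified parameter-recovery
experiments are possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.optimize import minimize
from scipy.special import gamma as gamma_fn
from sklearn.isotonic import IsotonicRegression

__all__ = [
    "ErrorModelTable",
    "default_error_table",
    "default_sd_curve",
    "weibull_error_logpdf",
    "weibull_error_logcdf",
    "sample_errors",
    "calibrate_error_model",
]


def _weibull_unit_sd(k: np.ndarray) -> np.ndarray:
    """SD of a Weibull(shape=k, scale=1) variate."""
    k = np.asarray(k, dtype=float)
    return np.sqrt(gamma_fn(1.0 + 2.0 / k) - gamma_fn(1.0 + 1.0 / k) ** 2)


@dataclass(frozen=True)
class ErrorModelTable:
    """Sensitivity-binned parameters of the reflected-Weibull error model.

    ``edges`` partitions [0, 40] dB into ``B = len(edges) - 1`` bins;
    ``shape`` (k) and ``scale`` (lam, dB) hold one positive value per bin.
    The derived ``shift`` (c) makes each bin's error mean-zero.  Bin
    dispersion (Weibull SD) must be non-increasing with sensitivity.
    """

    edges: np.ndarray
    shape: np.ndarray
    scale: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "edges", np.asarray(self.edges, dtype=float))
        object.__setattr__(self, "shape", np.asarray(self.shape, dtype=float))
        object.__setattr__(self, "scale", np.asarray(self.scale, dtype=float))
        if len(self.edges) != len(self.shape) + 1 or len(self.shape) != len(self.scale):
            raise ValueError("edges must have one more entry than shape/scale")
        if not (np.all(self.shape > 0) and np.all(self.scale > 0)):
            raise ValueError("shape and scale must be positive in every bin")
        if not np.all(np.diff(self.edges) > 0):
            raise ValueError("bin edges must be strictly increasing")
        sd = self.sd
        if np.any(np.diff(sd) > 1e-9):
            raise ValueError("error dispersion must be non-increasing with level")

    @property
    def n_bins(self) -> int:
        return len(self.shape)

    @property
    def shift(self) -> np.ndarray:
        """Mean-zero shift c = lam * Gamma(1 + 1/k), per bin."""
        return self.scale * gamma_fn(1.0 + 1.0 / self.shape)

    @property
    def sd(self) -> np.ndarray:
        """Error SD per bin (dB)."""
        return self.scale * _weibull_unit_sd(self.shape)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def bin_of(self, level) -> np.ndarray:
        """Bin index of each sensitivity level; levels are clipped into range."""
        level = np.clip(np.asarray(level, dtype=float), self.edges[0], self.edges[-1])
        return np.clip(
            np.searchsorted(self.edges, level, side="right") - 1, 0, self.n_bins - 1
        )

    def params_at(self, level):
        """(k, lam, c) arrays broadcast to the shape of ``level``."""
        b = self.bin_of(level)
        return self.shape[b], self.scale[b], self.shift[b]

    def scaled(self, factor: float) -> "ErrorModelTable":
        """Table with every bin's dispersion multiplied by ``factor``.

        Shapes are kept; scales (hence SDs and shifts) are multiplied.  Used
        to emulate populations that are more or less variable than the model
        assumes (e.g. an optimistic reference group of fastidious test
        takers).
        """
        if factor <= 0:
            raise ValueError("factor must be positive")
        return ErrorModelTable(self.edges, self.shape.copy(), self.scale * factor)

    # ---- serialization -------------------------------------------------
    def to_yaml(self, path) -> None:
        payload = {
            "edges": [float(e) for e in self.edges],
            "shape": [float(k) for k in self.shape],
            "scale": [float(s) for s in self.scale],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ErrorModelTable":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(payload["edges"], payload["shape"], payload["scale"])


def default_sd_curve(level) -> np.ndarray:
    """Default retest dispersion (dB SD) as a function of sensitivity.

    1.0 dB for level >= 30 dB, rising linearly to 6.0 dB at 10 dB, constant
    6.0 dB below.  Simple documented numbers capturing the direction and
    rough magnitude of perimetric heteroscedasticity.
    """
    level = np.asarray(level, dtype=float)
    return np.where(
        level >= 30.0,
        1.0,
        np.where(level <= 10.0, 6.0, 1.0 + 5.0 * (30.0 - level) / 20.0),
    )


def default_error_table() -> ErrorModelTable:
    """Default calibration of the error model.

    Seven bins over [0, 40] dB; per bin, the shape k grows with sensitivity
    (near-symmetric errors in healthy ranges, k = 3.6; strongly left-skewed
    in damaged ranges, k = 1.5) and the scale is set so that the bin SD
    matches :func:`default_sd_curve` at the bin center.
    """
    edges = np.array([0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 40.0])
    shape = np.array([1.5, 1.5, 1.8, 2.2, 2.6, 3.0, 3.6])
    centers = 0.5 * (edges[:-1] + edges[1:])
    scale = default_sd_curve(centers) / _weibull_unit_sd(shape)
    return ErrorModelTable(edges, shape, scale)


def weibull_error_logpdf(residual, level, table: ErrorModelTable) -> np.ndarray:
    """Log-density of the error model at ``residual`` given true ``level``.

    With (k, lam, c) from the bin of ``level`` and u = c - residual:
    log[(k/lam) (u/lam)^(k-1) exp(-(u/lam)^k)] for u > 0, -inf otherwise.
    """
    residual = np.asarray(residual, dtype=float)
    k, lam, c = table.params_at(level)
    u = c - residual
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(
            u > 0,
            np.log(k / lam) + (k - 1.0) * np.log(u / lam) - (u / lam) ** k,
            -np.inf,
        )
    return out


def weibull_error_logcdf(residual, level, table: ErrorModelTable) -> np.ndarray:
    """log P(error <= residual); the left-censoring term of the likelihood."""
    residual = np.asarray(residual, dtype=float)
    k, lam, c = table.params_at(level)
    u = c - residual
    # P(error <= z) = P(W >= c - z) = exp(-((c - z)/lam)^k) for z <= c, else 1
    return np.where(u > 0, -((np.maximum(u, 0.0) / lam) ** np.asarray(k)), 0.0)


def sample_errors(level, table: ErrorModelTable, rng: np.random.Generator) -> np.ndarray:
    """Draw mean-zero reflected-Weibull errors at the given true levels."""
    level = np.asarray(level, dtype=float)
    k, lam, c = table.params_at(level)
    return c - lam * rng.weibull(k, size=level.shape)


# ---------------------------------------------------------------------------
# calibration from test-retest data
# ---------------------------------------------------------------------------

def _fit_bin(errors: np.ndarray) -> tuple[float, float]:
    """Constrained MLE of (k, lam) for one bin of errors.

    The shift is tied to (k, lam) by the mean-zero constraint, so this is a
    two-parameter fit of e = c(k, lam) - W.  Optimized over (log k, log lam)
    by Nelder-Mead with a feasibility penalty when the support bound c does
    not cover the largest observed error.
    """
    errors = np.asarray(errors, dtype=float)
    spread = errors.std()
    if spread < 1e-9:
        raise ValueError("zero-spread errors: cannot calibrate a bin")
    e_max = errors.max()

    def nll(theta):
        k, lam = np.exp(theta)
        c = lam * gamma_fn(1.0 + 1.0 / k)
        if c <= e_max:
            return 1e9 + 1e3 * (e_max - c)
        u = c - errors
        return float(-np.sum(np.log(k / lam) + (k - 1) * np.log(u / lam) - (u / lam) ** k))

    k0 = 2.0
    lam0 = spread / float(_weibull_unit_sd(k0))
    best = None
    for k_start in (k0, 1.2, 3.5):
        lam_start = spread / float(_weibull_unit_sd(k_start))
        res = minimize(
            nll,
            np.log([k_start, lam_start]),
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    k, lam = np.exp(best.x)
    return float(k), float(lam)


def calibrate_error_model(
    test_retest, level_bins, min_pairs: int = 50
) -> ErrorModelTable:
    """Fit an :class:`ErrorModelTable` from paired test-retest measurements.

    Parameters
    ----------
    test_retest : DataFrame with columns ``true_level``, ``m1``, ``m2``
        (true sensitivity and two repeated measurements, dB).  Errors are
        pooled over both measurements.
    level_bins : array of bin edges over [0, 40] dB.
    min_pairs : minimum pairs required per bin.

    After per-bin MLE, bin SDs are made non-increasing in sensitivity by
    isotonic regression (pool-adjacent-violators, weighted by bin counts);
    scales are rescaled to the adjusted SDs with shapes kept.
    """
    edges = np.asarray(level_bins, dtype=float)
    levels = np.asarray(test_retest["true_level"], dtype=float)
    err = np.concatenate(
        [
            np.asarray(test_retest["m1"], dtype=float) - levels,
            np.asarray(test_retest["m2"], dtype=float) - levels,
        ]
    )
    lev2 = np.concatenate([levels, levels])
    idx = np.clip(np.searchsorted(edges, lev2, side="right") - 1, 0, len(edges) - 2)

    shapes, scales, counts = [], [], []
    for b in range(len(edges) - 1):
        e_b = err[idx == b]
        if len(e_b) < 2 * min_pairs:  # two measurements per pair
            raise ValueError(
                f"bin [{edges[b]}, {edges[b + 1]}) has {len(e_b) // 2} pairs "
                f"(< {min_pairs})"
            )
        k, lam = _fit_bin(e_b)
        shapes.append(k)
        scales.append(lam)
        counts.append(len(e_b))

    shapes = np.array(shapes)
    scales = np.array(scales)
    sd_fit = scales * _weibull_unit_sd(shapes)
    centers = 0.5 * (edges[:-1] + edges[1:])
    iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
    sd_adj = iso.fit_transform(centers, sd_fit, sample_weight=np.array(counts))
    scales = scales * sd_adj / sd_fit
    return ErrorModelTable(edges, shapes, scales)
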