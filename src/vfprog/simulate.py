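"""Synthetic longitudinal visual-field cohorts.

Emulates the structure of the longitudinal glaucoma perimetry datasets this
package targets: series of 7 / 9 / ~18 visits at roughly half-year
intervals, baseline fields from near-normal to advanced damage, localized
(sector-correlated) defects, depth-dependent skewed retest noise, and floor
censoring at 0 dB.  Every operation is reproducible from an explicit seed.

What is *not* simulated: the thresholding staircase itself, response errors
(false positives/negatives), learning and fatigue effects, or cataract-like
diffuse media change.  Passing tests on these cohorts therefore demonstrate
statistical correctness of the progression tests under the stated data
model, not clinical performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .errors import (
    ErrorModelTable,
    default_error_table,
    default_sd_curve,
    sample_errors,
)
from .model import DB_CEIL, DB_FLOOR, N_LOC, Grid24_2, VFSeries, make_grid

__all__ = [
    "NoiseModel",
    "CohortConfig",
    "default_template",
    "generate_cohort",
    "generate_test_retest",
    "reorder_in_time",
    "p3_like",
    "digs_like",
    "rotterdam_like",
]


@dataclass(frozen=True)
class NoiseModel:
    """Test-retest noise: skewed ("weibull") or symmetric ("gaussian").

    In weibull mode, errors are drawn from the reflected shifted Weibull
    family of :mod:`vfprog.errors` (mean zero, bounded above, long left
    tail), binned by true sensitivity.  In gaussian mode, errors are
    N(0, sd_curve(level)^2): same heteroscedasticity, no skew — useful for
    testing the ANSWERS likelihood under misspecification.  ``sd_scale``
    multiplies the dispersion everywhere (e.g. 0.5 emulates unusually
    reliable test takers).
    """

    mode: str = "weibull"
    table: ErrorModelTable = field(default_factory=default_error_table)
    sd_curve: Callable | None = None  # level -> SD (dB); default heteroscedastic
    sd_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("weibull", "gaussian"):
            raise ValueError(f"unknown noise mode {self.mode!r}")
        if self.sd_curve is None:
            object.__setattr__(self, "sd_curve", default_sd_curve)
        if self.sd_scale < 0:
            raise ValueError("sd_scale must be non-negative")

    def sd(self, level) -> np.ndarray:
        return self.sd_scale * np.asarray(self.sd_curve(level), dtype=float)

    def scaled(self, factor: float) -> "NoiseModel":
        return NoiseModel(self.mode, self.table, self.sd_curve, self.sd_scale * factor)

    def sample(self, level, rng: np.random.Generator) -> np.ndarray:
        """Mean-zero errors at the given true levels (dB)."""
        level = np.asarray(level, dtype=float)
        if self.sd_scale == 0.0:
            return np.zeros_like(level)
        if self.mode == "gaussian":
            return rng.normal(0.0, self.sd(level))
        table = self.table if self.sd_scale == 1.0 else self.table.scaled(self.sd_scale)
        return sample_errors(level, table, rng)


def default_template(grid: Grid24_2 | None = None) -> np.ndarray:
    """A normal-field template: ~33 dB centrally, mild eccentricity fall-off."""
    grid = grid or make_grid()
    ecc = np.hypot(grid.x_deg, grid.y_deg)
    return 33.5 - 0.12 * ecc


@dataclass
class CohortConfig:
    """Recipe for one synthetic cohort.

    ``defect_spec`` lists (sector, depth-dB) baseline defects; each eye's
    depth is the nominal depth times a Uniform(0.5, 1.5) draw, so damage
    varies across eyes but stays sector-correlated.  ``progression_spec``
    lists (sector, slope dB/year <= 0) deterioration applied to a fraction
    ``progression_fraction`` of eyes.  Visit times start at 0 and advance by
    ``interval_years`` with +/- ``interval_jitter`` relative uniform jitter
    (default layout: ~6-monthly visits).
    """

    n_eyes: int = 100
    n_visits: int = 7
    interval_years: float = 0.458  # ~5.5 months
    interval_jitter: float = 0.25
    baseline_template: np.ndarray | None = None
    defect_spec: list[tuple[int, float]] = field(default_factory=list)
    progression_spec: list[tuple[int, float]] = field(default_factory=list)
    progression_fraction: float = 0.0
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    def validate(self, grid: Grid24_2) -> None:
        if self.n_eyes < 1:
            raise ValueError("n_eyes must be positive")
        if self.n_visits < 3:
            raise ValueError("n_visits must be at least 3")
        if self.interval_years <= 0:
            raise ValueError("interval_years must be positive")
        if not 0.0 <= self.progression_fraction <= 1.0:
            raise ValueError("progression_fraction must be in [0, 1]")
        sectors = set(np.unique(grid.sector))
        for s, _depth in self.defect_spec:
            if s not in sectors:
                raise ValueError(f"defect_spec names unknown sector {s}")
        for s, slope in self.progression_spec:
            if s not in sectors:
                raise ValueError(f"progression_spec names unknown sector {s}")
            if slope > 0:
                raise ValueError("injected progression slopes must be <= 0 dB/year")


def generate_cohort(config: CohortConfig, grid: Grid24_2 | None = None) -> list[VFSeries]:
    """Generate ``config.n_eyes`` series with known true slopes.

    Each location's trajectory is baseline + slope * t + noise(true level),
    clipped to [0, 40] dB; the floor at 0 dB produces the left-censoring the
    ANSWERS likelihood must handle.  Fully reproducible from ``config.seed``.
    """
    grid = grid or make_grid()
    config.validate(grid)
    rng = np.random.default_rng(config.seed)
    template = (
        default_template(grid)
        if config.baseline_template is None
        else np.asarray(config.baseline_template, dtype=float)
    )
    if template.shape != (N_LOC,):
        raise ValueError("baseline_template must have 52 entries")

    series = []
    for i in range(config.n_eyes):
        baseline = template.copy()
        for s, depth in config.defect_spec:
            baseline[grid.sector == s] -= depth * rng.uniform(0.5, 1.5)
        baseline = np.clip(baseline, DB_FLOOR, DB_CEIL)

        slopes = np.zeros(N_LOC)
        if config.progression_spec and rng.uniform() < config.progression_fraction:
            for s, slope in config.progression_spec:
                slopes[grid.sector == s] = slope

        intervals = config.interval_years * (
            1.0 + rng.uniform(-config.interval_jitter, config.interval_jitter,
                              size=config.n_visits - 1)
        )
        times = np.concatenate([[0.0], np.cumsum(intervals)])

        true_levels = np.clip(
            baseline[None, :] + slopes[None, :] * times[:, None], DB_FLOOR, DB_CEIL
        )
        noisy = true_levels + config.noise.sample(true_levels, rng)
        values = np.clip(noisy, DB_FLOOR, DB_CEIL)
        series.append(
            VFSeries(
                series_id=f"sim{i:04d}",
                eye="OD",
                times=times,
                values=values,
                truth_slopes=slopes,
            )
        )
    return series


def generate_test_retest(
    n_pairs: int,
    level_grid,
    noise: NoiseModel,
    seed: int,
) -> pd.DataFrame:
    """Paired noisy measurements at known true sensitivities.

    Returns a DataFrame with columns ``true_level``, ``m1``, ``m2``
    (``n_pairs`` rows per grid level).  Measurements are *not* clipped to the
    instrument range: this table is the calibration input for
    :func:`vfprog.errors.calibrate_error_model`, and leaving it uncensored
    keeps the per-bin error distributions exactly the generating family.
    """
    level_grid = np.asarray(level_grid, dtype=float)
    if level_grid.size == 0:
        raise ValueError("level_grid must be non-empty")
    if np.any((level_grid < DB_FLOOR) | (level_grid > DB_CEIL)):
        raise ValueError("levels must lie within [0, 40] dB")
    rng = np.random.default_rng(seed)
    levels = np.repeat(level_grid, n_pairs)
    return pd.DataFrame(
        {
            "true_level": levels,
            "m1": levels + noise.sample(levels, rng),
            "m2": levels + noise.sample(levels, rng),
        }
    )


def reorder_in_time(series: VFSeries, rng) -> VFSeries:
    """Randomly permute the temporal order of a series' visual fields.

    The visit *times* stay fixed and the rows of the value matrix are
    permuted uniformly at random, destroying any systematic trend while
    preserving each location's marginal distribution.  True slopes no
    longer apply and are dropped.  ``rng`` may be a seed or a Generator.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    perm = rng.permutation(series.n_visits)
    return VFSeries(
        series_id=series.series_id,
        eye=series.eye,
        times=series.times.copy(),
        values=series.values[perm],
        truth_slopes=None,
    )


# ---------------------------------------------------------------------------
# Cohort presets emulating the three published dataset profiles
# ---------------------------------------------------------------------------

def _preset(n_eyes, n_visits, interval, defect_spec, seed) -> CohortConfig:
    return CohortConfig(
        n_eyes=n_eyes,
        n_visits=n_visits,
        interval_years=interval,
        defect_spec=defect_spec,
        seed=seed,
    )


def p3_like(n_eyes: int = 101, seed: int = 0) -> CohortConfig:
    """Early-glaucoma profile: 7 visits, ~5.5-month spacing, median MD ~ -0.5 dB."""
    return _preset(n_eyes, 7, 0.458, [(2, 3.0)], seed)


def digs_like(n_eyes: int = 150, seed: int = 0) -> CohortConfig:
    """Mixed-severity profile: 9 visits, ~6.4-month spacing, median MD ~ -0.9 dB."""
    return _preset(n_eyes, 9, 0.533, [(2, 3.0), (5, 2.0)], seed)


def rotterdam_like(n_eyes: int = 139, seed: int = 0) -> CohortConfig:
    """Advanced-glaucoma profile: 18 visits, ~6.3-month spacing, median MD ~ -7.7 dB."""
    return _preset(n_eyes, 18, 0.525, [(1, 11.0), (2, 14.0), (5, 13.0), (6, 12.0)], seed)
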