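"""Core data types for longitudinal 24-2 visual-field analysis.

The 24-2 test pattern of the Humphrey Field Analyzer samples 54 locations on
a 6-degree grid; the two locations falling on the physiological blind spot
(x = 15, y = +/-3 in right-eye convention) are excluded from progression
analysis, leaving the 52 locations used throughout this package.

All series are kept in right-eye (OD) coordinate convention.  For left eyes
the column layout of a series refers to the mirrored native locations
(x -> -x), so a single grid and a single spatial-weight matrix serve both
eyes; see :func:`vfprog.io.read_series`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

N_LOC = 52

#: rows of the 24-2 pattern, right-eye convention, top to bottom.
#: y = +/-3 rows extend to x = -27 (nasal step); the blind spot sits at
#: (15, +/-3) and is removed below.
_PATTERN_ROWS: dict[int, list[int]] = {
    21: [-9, -3, 3, 9],
    15: [-15, -9, -3, 3, 9, 15],
    9: [-21, -15, -9, -3, 3, 9, 15, 21],
    3: [-27, -21, -15, -9, -3, 3, 9, 15, 21],
    -3: [-27, -21, -15, -9, -3, 3, 9, 15, 21],
    -9: [-21, -15, -9, -3, 3, 9, 15, 21],
    -15: [-15, -9, -3, 3, 9, 15],
    -21: [-9, -3, 3, 9],
}

_BLIND_SPOT = {(15, 3), (15, -3)}

DB_FLOOR = 0.0
DB_CEIL = 40.0


@dataclass(frozen=True)
class Grid24_2:
    """Static geometry of the 52 analysed 24-2 locations.

    Attributes
    ----------
    location_id : (52,) int array, 1-based ids in reading order
        (top row first, left to right).
    x_deg, y_deg : (52,) float arrays, visual-field coordinates in degrees,
        right-eye convention (positive x temporal, positive y superior).
    sector : (52,) int array in 1..6, nerve-fiber-bundle sector label.
    is_superior : (52,) bool array, True above the horizontal midline.
    """

    location_id: np.ndarray
    x_deg: np.ndarray
    y_deg: np.ndarray
    sector: np.ndarray
    is_superior: np.ndarray

    @property
    def n(self) -> int:
        return len(self.location_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "location_id": self.location_id,
                "x_deg": self.x_deg,
                "y_deg": self.y_deg,
                "sector": self.sector,
            }
        )

    def sector_members(self, s: int) -> np.ndarray:
        """Indices (0-based) of the locations in sector ``s``."""
        return np.flatnonzero(self.sector == s)


def _sector_of(x: float, y: float) -> int:
    """Six-sector nerve-fiber-bundle partition by field angle.

    The arrangement follows the familiar six-region bundle maps (temporal
    raphe splitting the horizontal midline, arcuate bundles above and below,
    nasal/papillomacular regions near the midline): 60-degree angular wedges
    of the field, numbered 1..3 superior-to-temporal-to-nasal and 4..6
    mirrored inferiorly.  The exact published bundle maps differ in detail;
    this partition is a documented stand-in with the same anatomy-driven
    structure (within-sector correlation, respect of the horizontal raphe).
    """
    theta = np.degrees(np.arctan2(y, x)) % 360.0
    return int(theta // 60.0) + 1


def make_grid() -> Grid24_2:
    """Build the fixed 52-location 24-2 grid (deterministic).

    Identical, entry for entry, to the plain-text fixture shipped at
    ``vfprog/data/grid24_2.csv``.
    """
    xs, ys = [], []
    for y in sorted(_PATTERN_ROWS, reverse=True):
        for x in _PATTERN_ROWS[y]:
            if (x, y) in _BLIND_SPOT:
                continue
            xs.append(float(x))
            ys.append(float(y))
    x = np.array(xs)
    y = np.array(ys)
    sector = np.array([_sector_of(a, b) for a, b in zip(x, y)], dtype=int)
    return Grid24_2(
        location_id=np.arange(1, len(x) + 1),
        x_deg=x,
        y_deg=y,
        sector=sector,
        is_superior=y > 0,
    )


def load_grid_fixture() -> pd.DataFrame:
    """The shipped plain-text grid table (location_id, x_deg, y_deg, sector)."""
    with resources.files("vfprog").joinpath("data/grid24_2.csv").open() as fh:
        return pd.read_csv(fh)


@dataclass
class VFSeries:
    """One eye's longitudinal visual-field record.

    Attributes
    ----------
    series_id : str
    eye : {"OD", "OS"}
    times : (T,) float array, visit times in years from baseline,
        strictly increasing with ``times[0] == 0``.
    values : (T, 52) float array of sensitivities in dB, within [0, 40].
    truth_slopes : optional (52,) array of true dB/year slopes
        (synthetic series only; invalidated by temporal re-ordering).
    """

    series_id: str
    eye: str
    times: np.ndarray
    values: np.ndarray
    truth_slopes: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.eye not in ("OD", "OS"):
            raise ValueError(f"eye must be 'OD' or 'OS', got {self.eye!r}")
        if self.values.ndim != 2 or self.values.shape[1] != N_LOC:
            raise ValueError(
                f"values must be (visits, {N_LOC}), got {self.values.shape}"
            )
        if len(self.times) != self.values.shape[0]:
            raise ValueError("times and values disagree on number of visits")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("visit times must be strictly increasing")

    @property
    def n_visits(self) -> int:
        return len(self.times)

    def normalized(self) -> "VFSeries":
        """Shift times so the first visit is at 0 years."""
        return VFSeries(
            self.series_id,
            self.eye,
            self.times - self.times[0],
            self.values.copy(),
            None if self.truth_slopes is None else self.truth_slopes.copy(),
        )


@dataclass
class ProgressionResult:
    """Outcome of one progression test on one series.

    ``S`` is the combined statistic -sum(ln p) over the 52 local p-values
    (for ANSWERS this is the statistic usually written I-minus).  ``p_global``
    is NaN when ``status == "failed"``.
    """

    series_id: str
    method: str  # {poplr, answers, answer, answers_perm}
    S: float
    p_global: float
    slopes: np.ndarray
    p_local: np.ndarray
    status: str = "ok"  # {ok, failed}
    extras: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def clamp_db(values: np.ndarray, warn: bool = True) -> np.ndarray:
    """Clamp sensitivities to the instrument range [0, 40] dB."""
    values = np.asarray(values, dtype=float)
    n_out = int(np.sum((values < DB_FLOOR) | (values > DB_CEIL)))
    if n_out and warn:
        logger.warning("clamped %d sensitivity value(s) to [0, 40] dB", n_out)
    return np.clip(values, DB_FLOOR, DB_CEIL)


def md_proxy(series: VFSeries, template: np.ndarray) -> np.ndarray:
    """Template-relative mean deviation, one value per visit.

    The unweighted mean of (observed - template) over the 52 locations: a
    simple global severity index comparable to the instrument's MD when the
    template approximates an age-normal field.  Not an age-corrected,
    variance-weighted normative MD.
    """
    template = np.asarray(template, dtype=float)
    if template.shape != (N_LOC,):
        raise ValueError(f"template must have {N_LOC} entries, got {template.shape}")
    return (series.values - template).mean(axis=1)
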