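"""CSV/YAML formats for series, results, and curves.

The series table follows common perimetry-research CSV exports: one row per
visit with columns ``series_id, eye, date, L1..L52``.  The L-columns are in
the fixed grid order of :func:`vfprog.model.make_grid`; for left eyes (OS)
column ``Li`` refers to the mirrored native location (x -> -x), so the
in-memory matrix is already in right-eye convention for both eyes and a
single grid serves all series.
"""

from __future__ import annotations

import datetime as _dt
import logging

import numpy as np
import pandas as pd

from .model import N_LOC, ProgressionResult, VFSeries, clamp_db

logger = logging.getLogger(__name__)

_L_COLS = [f"L{i}" for i in range(1, N_LOC + 1)]
_HEADER = ["series_id", "eye", "date"] + _L_COLS

DAYS_PER_YEAR = 365.25


def write_series(path, series_list, start_date: str = "2010-01-01") -> None:
    """Write series to the SeriesTable CSV dialect.

    Times (years from baseline) are converted to ISO-8601 dates offset from
    ``start_date``; rows of each series are written in date order.
    """
    base = _dt.date.fromisoformat(start_date)
    rows = []
    for s in series_list:
        for t, vals in zip(s.times, s.values):
            date = base + _dt.timedelta(days=round(t * DAYS_PER_YEAR))
            rows.append([s.series_id, s.eye, date.isoformat()] + list(vals))
    pd.DataFrame(rows, columns=_HEADER).to_csv(path, index=False)


def read_series(path) -> list[VFSeries]:
    """Read a SeriesTable CSV into normalized :class:`VFSeries` objects.

    Dates become fractional years from each series' first visit; values
    outside [0, 40] dB are clamped with a logged warning.  Two visits on
    the same day are kept, ordered by file position, with the second
    shifted by one day (warned).
    """
    df = pd.read_csv(path)
    missing = [c for c in _HEADER if c not in df.columns]
    if missing:
        raise ValueError(f"malformed series file: missing column(s) {missing}")
    out = []
    for sid, g in df.groupby("series_id", sort=False):
        g = g.reset_index(drop=True)
        eye = str(g["eye"].iloc[0])
        dates = [_dt.date.fromisoformat(d) for d in g["date"]]
        order = np.argsort([d.toordinal() for d in dates], kind="stable")
        dates = [dates[i] for i in order]
        days = np.array([d.toordinal() for d in dates], dtype=float)
        dup = np.flatnonzero(np.diff(days) == 0)
        if dup.size:
            logger.warning("series %s: %d duplicate visit date(s)", sid, dup.size)
            for i in dup:
                days[i + 1 :] += 1.0
        times = (days - days[0]) / DAYS_PER_YEAR
        values = clamp_db(g[_L_COLS].to_numpy(dtype=float)[order])
        out.append(VFSeries(str(sid), eye, times, values))
    return out


def write_truth(path, series_list) -> None:
    """Sidecar CSV of true slopes: series_id, location_id, slope (dB/year)."""
    rows = []
    for s in series_list:
        if s.truth_slopes is None:
            continue
        for loc, slope in enumerate(s.truth_slopes, start=1):
            rows.append([s.series_id, loc, slope])
    pd.DataFrame(rows, columns=["series_id", "location_id", "slope"]).to_csv(
        path, index=False
    )


def results_to_frames(results) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Global and per-location long tables for a list of ProgressionResults."""
    glob = pd.DataFrame(
        [
            {
                "series_id": r.series_id,
                "method": r.method,
                "S": r.S,
                "p_global": r.p_global,
                "status": r.status,
                **{k: v for k, v in r.extras.items()},
            }
            for r in results
        ]
    )
    local_rows = []
    for r in results:
        for loc in range(N_LOC):
            local_rows.append(
                [r.series_id, r.method, loc + 1, r.slopes[loc], r.p_local[loc]]
            )
    local = pd.DataFrame(
        local_rows, columns=["series_id", "method", "location_id", "slope", "p_local"]
    )
    return glob, local


def read_global_p(path) -> pd.DataFrame:
    """Read a global results CSV back (series_id, method, S, p_global, status)."""
    df = pd.read_csv(path)
    needed = {"series_id", "method", "p_global", "status"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"malformed results file: missing column(s) {sorted(missing)}")
    return df


def curves_to_frame(method: str, curves) -> pd.DataFrame:
    """Tidy frame of one method's evaluation curves."""
    return pd.DataFrame(
        {
            "method": method,
            "alpha": curves.alpha_grid,
            "positive_rate": (
                np.full_like(curves.alpha_grid, np.nan)
                if curves.positive_rate is None
                else curves.positive_rate
            ),
            "fpr": (
                np.full_like(curves.alpha_grid, np.nan)
                if curves.false_positive_rate is None
                else curves.false_positive_rate
            ),
        }
    )
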