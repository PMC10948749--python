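"""Reading, validation, resampling and writing of CGM traces and study tables.

All downstream stages consume the in-memory representations defined here:
a :class:`GlucoseTrace` per subject (a timezone-naive, strictly increasing
timestamped glucose series in mg/dL), plus plain :class:`pandas.DataFrame`
tables for the per-subject biomarker panel and the per-day activity log.

CSV dialects are fixed: UTF-8, LF line endings, ``.`` decimal separator.
Trace files carry the header ``subject_id,timestamp,glucose_mgdl`` with
ISO-8601 timestamps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sensor reporting range in mg/dL; readings outside are treated as invalid.
GLUCOSE_MIN = 40.0
GLUCOSE_MAX = 500.0

COHORTS = ("healthy", "prediabetic")

TRACE_COLUMNS = ["subject_id", "timestamp", "glucose_mgdl"]
PANEL_COLUMNS = [
    "subject_id",
    "cohort",
    "hba1c",
    "ogtt_2h",
    "homa_ir",
    "hscrp",
    "cortisol",
    "fbg_baseline",
    "fbg_end",
]
ACTIVITY_COLUMNS = ["subject_id", "date", "steps", "hr_bpm", "sleep_min"]


class TraceFormatError(ValueError):
    """Raised for malformed trace files (wrong header, no valid rows)."""


class EmptyWindowError(ValueError):
    """Raised when an analysis window contains no data."""


@dataclass
class GlucoseTrace:
    """One subject's timestamped glucose series.

    Parameters
    ----------
    subject_id : str
        Opaque subject identifier.
    samples : pandas.Series
        Glucose in mg/dL indexed by a timezone-naive ``DatetimeIndex`` with
        strictly increasing timestamps.  NaN marks a missing grid point
        (only produced by :func:`resample_to_grid`).
    cohort : str, optional
        ``"healthy"`` or ``"prediabetic"`` when known.
    """

    subject_id: str
    samples: pd.Series
    cohort: Optional[str] = None
    interval_min: Optional[float] = field(default=None, compare=False)
    #: calendar day of sensor activation (study day 1); defaults to the
    #: first sample's date and is preserved through resampling/windowing
    activation_date: Optional[date] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not isinstance(self.samples, pd.Series):
            self.samples = pd.Series(dict(self.samples), dtype=float)
        self.samples = self.samples.astype(float)
        idx = pd.DatetimeIndex(self.samples.index)
        if idx.tz is not None:
            idx = idx.tz_localize(None)
        self.samples.index = idx
        if len(idx) > 1 and not idx.is_monotonic_increasing:
            raise ValueError("trace timestamps must be increasing")
        if len(idx) > 1 and idx.has_duplicates:
            raise ValueError("trace timestamps must be strictly increasing")
        vals = self.samples.to_numpy()
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < GLUCOSE_MIN or finite.max() > GLUCOSE_MAX):
            raise ValueError(
                f"glucose outside sensor range [{GLUCOSE_MIN:g}, {GLUCOSE_MAX:g}] mg/dL"
            )
        if self.cohort is not None and self.cohort not in COHORTS:
            raise ValueError(f"unknown cohort {self.cohort!r}; expected one of {COHORTS}")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def start(self) -> pd.Timestamp:
        return self.samples.index[0]

    @property
    def n_days(self) -> int:
        """Number of calendar days spanned (inclusive)."""
        idx = self.samples.index
        return (idx[-1].date() - idx[0].date()).days + 1

    @property
    def day1(self) -> date:
        """Study day 1: the activation date if known, else the first sample's day."""
        return self.activation_date or self.start.date()

    def with_samples(self, samples: pd.Series, **kw) -> "GlucoseTrace":
        return GlucoseTrace(
            subject_id=self.subject_id,
            samples=samples,
            cohort=self.cohort,
            interval_min=kw.get("interval_min", self.interval_min),
            activation_date=kw.get("activation_date", self.day1),
        )


# ---------------------------------------------------------------------------
# trace CSV


def read_trace_csv(path: str | Path) -> list[GlucoseTrace]:
    """Read a trace CSV into one :class:`GlucoseTrace` per subject.

    Rows with unparseable timestamps or glucose outside the sensor range
    [40, 500] mg/dL are dropped; the drop count is reported through the
    module logger.

    Raises
    ------
    TraceFormatError
        If the header is not ``subject_id,timestamp,glucose_mgdl`` or the
        file contains no valid rows.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str})
    if list(df.columns) != TRACE_COLUMNS:
        raise TraceFormatError(
            f"{path}: expected header {','.join(TRACE_COLUMNS)}, got {','.join(df.columns)}"
        )
    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    glu = pd.to_numeric(df["glucose_mgdl"], errors="coerce")
    ok = ts.notna() & glu.notna() & (glu >= GLUCOSE_MIN) & (glu <= GLUCOSE_MAX)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("%s: dropped %d invalid row(s)", path.name, n_dropped)
    df = pd.DataFrame({"subject_id": df["subject_id"], "timestamp": ts, "glucose": glu})[ok]
    if df.empty:
        raise TraceFormatError(f"{path}: no valid rows")
    traces = []
    for sid, grp in df.groupby("subject_id", sort=True):
        grp = grp.sort_values("timestamp")
        samples = pd.Series(
            grp["glucose"].to_numpy(), index=pd.DatetimeIndex(grp["timestamp"], name=None)
        )
        samples.index.name = None
        traces.append(GlucoseTrace(subject_id=str(sid), samples=samples))
    return traces


def write_trace_csv(traces: Iterable[GlucoseTrace] | GlucoseTrace, path: str | Path) -> None:
    """Write traces in the fixed trace-CSV dialect (missing points omitted)."""
    if isinstance(traces, GlucoseTrace):
        traces = [traces]
    frames = []
    for tr in traces:
        s = tr.samples.dropna()
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": tr.subject_id,
                    "timestamp": s.index.strftime("%Y-%m-%dT%H:%M:%S"),
                    "glucose_mgdl": s.to_numpy(),
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    _write_csv(out, path)


# ---------------------------------------------------------------------------
# panel / activity CSV


def _write_csv(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        df.to_csv(fh, index=False, lineterminator="\n")


def read_panel_csv(path: str | Path) -> pd.DataFrame:
    """Read the per-subject biomarker panel (one row per subject)."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise TraceFormatError(f"{path}: panel CSV missing columns {missing}")
    return df


def write_panel_csv(panel: pd.DataFrame, path: str | Path) -> None:
    _write_csv(panel, path)


def read_activity_csv(path: str | Path) -> pd.DataFrame:
    """Read the per-subject-day activity table (steps, heart rate, sleep)."""
    df = pd.read_csv(path, dtype={"subject_id": str}, parse_dates=["date"])
    missing = [c for c in ACTIVITY_COLUMNS if c not in df.columns]
    if missing:
        raise TraceFormatError(f"{path}: activity CSV missing columns {missing}")
    return df


def write_activity_csv(activity: pd.DataFrame, path: str | Path) -> None:
    out = activity.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    _write_csv(out, path)


# ---------------------------------------------------------------------------
# resampling and windowing


def resample_to_grid(
    trace: GlucoseTrace, interval_min: float = 15.0, max_gap_min: float = 60.0
) -> GlucoseTrace:
    """Resample a trace onto a regular grid by linear interpolation.

    The grid is anchored at local midnight of the first sample's day and
    steps by ``interval_min`` through the last observation.  Grid points
    farther than ``max_gap_min`` from every observation are emitted as NaN;
    interpolation never bridges such gaps, and nothing is extrapolated
    before the first or after the last observation.
    """
    if interval_min <= 0:
        raise ValueError("interval must be positive")
    obs = trace.samples.dropna()
    if obs.empty:
        raise ValueError("cannot resample an empty trace")
    t0 = obs.index[0].normalize()
    grid = pd.date_range(t0, obs.index[-1], freq=pd.Timedelta(minutes=interval_min))
    obs_t = obs.index.view("int64") / 1e9 / 60.0  # minutes
    grid_t = grid.view("int64") / 1e9 / 60.0
    vals = np.interp(grid_t, obs_t, obs.to_numpy())
    # mask points with no observation within max_gap on either side of the
    # bracketing interval, or beyond the observed extent
    left = np.searchsorted(obs_t, grid_t, side="right") - 1
    right = left + 1
    left_ok = left >= 0
    right_ok = right < len(obs_t)
    dist_left = np.where(left_ok, grid_t - obs_t[np.clip(left, 0, None)], np.inf)
    dist_right = np.where(right_ok, obs_t[np.clip(right, None, len(obs_t) - 1)] - grid_t, np.inf)
    exact = np.isin(grid_t, obs_t)
    # a grid point is valid if it coincides with an observation, or the
    # bracketing observations are both within max_gap (no long-gap bridging)
    bracket_ok = left_ok & right_ok & (dist_left <= max_gap_min) & (dist_right <= max_gap_min)
    vals = np.where(exact | bracket_ok, vals, np.nan)
    samples = pd.Series(vals, index=grid)
    return trace.with_samples(samples, interval_min=interval_min)


def analysis_window(
    trace: GlucoseTrace,
    start_day: int = 2,
    end_day: int = 14,
    activation_date: Optional[date] = None,
) -> GlucoseTrace:
    """Restrict a trace to study days ``start_day``..``end_day`` inclusive.

    Day 1 is the calendar day of sensor activation (by default the day of
    the first sample), so the default window of days 2-14 discards the
    first calendar day of sensor output and anything beyond two weeks.

    Raises
    ------
    EmptyWindowError
        If the trace spans fewer than two calendar days or the window is
        empty.
    """
    if start_day < 1 or end_day < start_day:
        raise ValueError("require 1 <= start_day <= end_day")
    if activation_date is None:
        activation_date = trace.activation_date
    if activation_date is None:
        activation_date = trace.start.date()
        if trace.n_days < 2:
            raise EmptyWindowError(f"{trace.subject_id}: trace spans fewer than 2 days")
    lo = pd.Timestamp(activation_date) + timedelta(days=start_day - 1)
    hi = pd.Timestamp(activation_date) + timedelta(days=end_day)  # exclusive
    out = trace.samples[(trace.samples.index >= lo) & (trace.samples.index < hi)]
    if out.dropna().empty:
        raise EmptyWindowError(f"{trace.subject_id}: empty analysis window")
    return trace.with_samples(out, activation_date=activation_date)


def day_groups(trace: GlucoseTrace) -> "pd.core.groupby.SeriesGroupBy":
    """Group a trace's samples by calendar date (local midnight boundary)."""
    return trace.samples.groupby(trace.samples.index.date)


def study_day_index(trace: GlucoseTrace, activation_date: Optional[date] = None) -> pd.Series:
    """Map each sample to its 1-based study-day number."""
    if activation_date is None:
        activation_date = trace.start.date()
    days = (pd.Series(trace.samples.index.date, index=trace.samples.index) - activation_date).apply(
        lambda d: d.days + 1
    )
    return days
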