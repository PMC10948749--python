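"""Glycemic-variability index engine.

Per-day metrics (mean, SD/CV, time-in-range fractions, MAGE, J-index,
LBGI/HBGI, CONGA) and cross-day aggregates (ADRR, MODD) for gridded CGM
traces.  All per-day functions accept a 1-D array of glucose readings in
mg/dL in which NaN marks a missing grid point; they return the documented
undefined-day marker (NaN) rather than raising when a day is degenerate.

Conventions fixed here and used throughout:

* sample standard deviation (``ddof=1``) everywhere;
* time-in-range percentages are reading-based (valid because traces are
  resampled to a uniform grid first) with closed range boundaries, so
  TAR is strictly ``> hi`` and TBR strictly ``< lo``;
* MAGE uses the classic turning-point scan with the day-SD qualification
  threshold, averaging both upward and downward excursions;
* the blood-glucose risk transform uses the standard mg/dL constants
  a=1.509, b=1.084, c=5.381.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from cgmetrics.io import GLUCOSE_MAX, GLUCOSE_MIN, GlucoseTrace

#: Minimum fraction of grid points that must be present for a calendar day
#: to contribute to per-day summaries.
DEFAULT_VALID_FRACTION = 0.70

DAILY_INDEX_COLUMNS = [
    "subject_id",
    "day_index",
    "mean_glucose",
    "sd",
    "cv",
    "tir",
    "rtir",
    "tar",
    "tbr",
    "mage",
    "j_index",
    "lbgi",
    "hbgi",
    "conga_n",
    "valid_fraction",
]


@dataclass(frozen=True)
class RiskTransform:
    """Symmetrizing blood-glucose risk transform.

    ``f(BG) = a * ((ln BG)**b - c)`` maps the clinically asymmetric
    glucose scale onto a symmetric risk space with f = 0 near 112.5
    mg/dL; the risk is ``r = 10 * f**2`` split into a low-glucose branch
    (f < 0) and a high-glucose branch (f > 0).
    """

    a: float = 1.509
    b: float = 1.084
    c: float = 5.381

    def f(self, bg):
        bg = np.asarray(bg, dtype=float)
        return self.a * (np.log(bg) ** self.b - self.c)

    def risk(self, bg):
        return 10.0 * self.f(bg) ** 2

    def low_high(self, bg):
        """Return ``(rl, rh)``: the low/high risk branches, one of which is 0."""
        fv = self.f(bg)
        r = 10.0 * fv**2
        return np.where(fv < 0, r, 0.0), np.where(fv > 0, r, 0.0)


RISK_TRANSFORM = RiskTransform()


def _clean(day: Sequence[float]) -> np.ndarray:
    arr = np.asarray(day, dtype=float)
    return arr[np.isfinite(arr)]


# ---------------------------------------------------------------------------
# per-day indices


def range_fractions(day: Sequence[float], lo: float = 70.0, hi: float = 180.0):
    """Percent of readings in [lo, hi], above hi, and below lo.

    Boundary values count as in range.  Returns ``(nan, nan, nan)`` when
    the day has no readings.
    """
    vals = _clean(day)
    if vals.size == 0:
        return (np.nan, np.nan, np.nan)
    n = vals.size
    above = 100.0 * np.count_nonzero(vals > hi) / n
    below = 100.0 * np.count_nonzero(vals < lo) / n
    return (100.0 - above - below, above, below)


def gv_sd_cv(day: Sequence[float]):
    """Within-day glycemic variability: ``(sample SD, CV%)``.

    CV = 100 * SD / mean.  Undefined (NaN, NaN) with fewer than two
    readings.
    """
    vals = _clean(day)
    if vals.size < 2:
        return (np.nan, np.nan)
    sd = float(np.std(vals, ddof=1))
    return (sd, 100.0 * sd / float(np.mean(vals)))


def _turning_points(vals: np.ndarray) -> np.ndarray:
    """Indices of interior local extrema of a sequence.

    Plateaus are collapsed by carrying the previous direction through
    zero differences, so adjacent same-direction segments merge into one.
    """
    d = np.sign(np.diff(vals))
    # carry direction through flats
    direction = np.zeros_like(d)
    cur = 0.0
    for i, s in enumerate(d):
        if s != 0:
            cur = s
        direction[i] = cur
    tps = []
    for i in range(1, len(direction)):
        if direction[i] != 0 and direction[i - 1] != 0 and direction[i] != direction[i - 1]:
            tps.append(i)
    return np.asarray(tps, dtype=int)


def mage(day: Sequence[float], threshold_sd: Optional[float] = None) -> float:
    """Mean amplitude of glycemic excursions.

    Classic turning-point method: locate alternating interior peaks and
    nadirs of the (unsmoothed) day profile, measure the amplitude of each
    nadir-to-peak and peak-to-nadir swing (including the swings from the
    first reading to the first turning point and from the last turning
    point to the last reading), and average the amplitudes strictly
    greater than the day's sample SD.  Returns 0 for a monotone or
    constant day, or when no excursion qualifies; NaN with fewer than
    three readings.

    ``threshold_sd`` overrides the qualification threshold (defaults to
    the day's own SD).
    """
    vals = _clean(day)
    if vals.size < 3:
        return np.nan
    sd = float(np.std(vals, ddof=1)) if threshold_sd is None else float(threshold_sd)
    tps = _turning_points(vals)
    if tps.size == 0:
        return 0.0
    nodes = np.concatenate(([0], tps, [len(vals) - 1]))
    amps = np.abs(np.diff(vals[nodes]))
    qual = amps[amps > sd]
    return float(qual.mean()) if qual.size else 0.0


def j_index(mean: float, sd: float) -> float:
    """J-index = 0.001 * (mean + SD)^2 (mg/dL formulation)."""
    if mean <= 0 or sd < 0:
        raise ValueError("require mean > 0 and sd >= 0")
    return 0.001 * (mean + sd) ** 2


def bg_risk(bg: float, transform: RiskTransform = RISK_TRANSFORM):
    """Low/high risk ``(rl, rh)`` of a single reading; at most one is nonzero."""
    bg = float(bg)
    if not (GLUCOSE_MIN <= bg <= GLUCOSE_MAX):
        raise ValueError(f"glucose {bg} outside sensor range [{GLUCOSE_MIN}, {GLUCOSE_MAX}]")
    rl, rh = transform.low_high(bg)
    return float(rl), float(rh)


def lbgi_hbgi(day: Sequence[float], transform: RiskTransform = RISK_TRANSFORM):
    """LBGI and HBGI: mean low and high risk over the day's readings."""
    vals = _clean(day)
    if vals.size == 0:
        return (np.nan, np.nan)
    rl, rh = transform.low_high(vals)
    return (float(rl.mean()), float(rh.mean()))


def conga(day: Sequence[float], lag_hours: float = 1.0, interval_min: float = 15.0) -> float:
    """CONGA(n): sample SD of differences between readings ``n`` hours apart.

    Operates on a day's gridded readings; pairs with either value missing
    are skipped.  NaN when fewer than two valid lagged pairs exist (e.g.
    the day does not span the lag).
    """
    arr = np.asarray(day, dtype=float)
    k = int(round(lag_hours * 60.0 / interval_min))
    if k <= 0:
        raise ValueError("lag must exceed the grid interval")
    if arr.size <= k:
        return np.nan
    diffs = arr[k:] - arr[:-k]
    diffs = diffs[np.isfinite(diffs)]
    if diffs.size < 2:
        return np.nan
    return float(np.std(diffs, ddof=1))


# ---------------------------------------------------------------------------
# cross-day aggregates


def adrr(days: Iterable[Sequence[float]], transform: RiskTransform = RISK_TRANSFORM) -> float:
    """Average daily risk range.

    For each day with at least one reading, the daily risk range is
    ``max(rl) + max(rh)`` over the day's readings; ADRR is the mean of
    the daily risk ranges.  NaN when no day is valid.
    """
    ranges = []
    for day in days:
        vals = _clean(day)
        if vals.size == 0:
            continue
        rl, rh = transform.low_high(vals)
        ranges.append(float(rl.max()) + float(rh.max()))
    return float(np.mean(ranges)) if ranges else np.nan


def modd(days: Sequence[Sequence[float]]) -> float:
    """Mean of daily differences.

    ``days`` is a sequence of consecutive calendar days on a shared grid
    (equal length, same clock times).  MODD is the mean absolute
    difference between matched clock times on consecutive day pairs,
    skipping pairs where either value is missing.  NaN when no aligned
    pair exists.
    """
    mat = [np.asarray(d, dtype=float) for d in days]
    if len(mat) < 2:
        return np.nan
    n = {len(d) for d in mat}
    if len(n) != 1:
        raise ValueError("all days must share one grid length")
    diffs = []
    for a, b in zip(mat[:-1], mat[1:]):
        d = np.abs(b - a)
        diffs.append(d[np.isfinite(d)])
    flat = np.concatenate(diffs) if diffs else np.array([])
    return float(flat.mean()) if flat.size else np.nan


# ---------------------------------------------------------------------------
# per-trace drivers


def _day_matrix(trace: GlucoseTrace, interval_min: float) -> pd.DataFrame:
    """Pivot a gridded trace into a (date x time-of-day) matrix."""
    s = trace.samples
    df = pd.DataFrame(
        {"date": s.index.date, "tod": s.index.hour * 60 + s.index.minute, "glucose": s.to_numpy()}
    )
    return df.pivot_table(index="date", columns="tod", values="glucose", dropna=False)


def daily_indices(
    trace: GlucoseTrace,
    conga_lag_hours: float = 1.0,
    valid_fraction: float = DEFAULT_VALID_FRACTION,
    activation_date=None,
) -> pd.DataFrame:
    """All per-day indices for one gridded trace.

    One row per calendar day with at least one reading; days whose
    fraction of present grid points falls below ``valid_fraction`` are
    flagged ``valid=False`` and excluded from cross-day aggregation by
    :func:`subject_summary`.
    """
    if trace.interval_min is None:
        raise ValueError("trace must be resampled to a grid first (resample_to_grid)")
    interval = trace.interval_min
    pts_per_day = int(round(24 * 60 / interval))
    if activation_date is None:
        activation_date = trace.day1
    mat = _day_matrix(trace, interval)
    rows = []
    for day_date, row in mat.iterrows():
        vals = row.to_numpy(dtype=float)
        present = int(np.isfinite(vals).sum())
        if present == 0:
            continue
        frac = present / pts_per_day
        mean = float(np.nanmean(vals))
        sd, cv = gv_sd_cv(vals)
        tir, tar, tbr = range_fractions(vals, 70.0, 180.0)
        rtir, _, _ = range_fractions(vals, 70.0, 110.0)
        lbgi, hbgi = lbgi_hbgi(vals)
        rows.append(
            {
                "subject_id": trace.subject_id,
                "day_index": (day_date - activation_date).days + 1,
                "mean_glucose": mean,
                "sd": sd,
                "cv": cv,
                "tir": tir,
                "rtir": rtir,
                "tar": tar,
                "tbr": tbr,
                "mage": mage(vals),
                "j_index": j_index(mean, sd) if np.isfinite(sd) else np.nan,
                "lbgi": lbgi,
                "hbgi": hbgi,
                "conga_n": conga(vals, conga_lag_hours, interval),
                "valid_fraction": frac,
                "valid": frac >= valid_fraction,
            }
        )
    return pd.DataFrame(rows, columns=DAILY_INDEX_COLUMNS + ["valid"])


def subject_summary(
    trace: GlucoseTrace,
    conga_lag_hours: float = 1.0,
    valid_fraction: float = DEFAULT_VALID_FRACTION,
    activation_date=None,
) -> pd.Series:
    """Cross-day aggregates for one gridded trace.

    Means of every per-day index over valid days, plus ADRR and MODD
    computed from the valid days' gridded readings (MODD only across
    consecutive valid day pairs).
    """
    daily = daily_indices(trace, conga_lag_hours, valid_fraction, activation_date)
    valid = daily[daily["valid"]]
    mat = _day_matrix(trace, trace.interval_min)
    if activation_date is None:
        activation_date = trace.day1
    day_of = {d: (d - activation_date).days + 1 for d in mat.index}
    valid_days = set(valid["day_index"])
    day_rows = [mat.loc[d].to_numpy(dtype=float) for d in mat.index if day_of[d] in valid_days]
    # MODD only across consecutive valid calendar days
    modd_pairs = []
    order = [d for d in mat.index if day_of[d] in valid_days]
    for a, b in zip(order[:-1], order[1:]):
        if (b - a).days == 1:
            modd_pairs.append(
                np.abs(mat.loc[b].to_numpy(dtype=float) - mat.loc[a].to_numpy(dtype=float))
            )
    if modd_pairs:
        cat = np.concatenate([p[np.isfinite(p)] for p in modd_pairs])
        modd_val = float(cat.mean()) if cat.size else np.nan
    else:
        modd_val = np.nan
    out = {"subject_id": trace.subject_id, "n_valid_days": len(valid)}
    for col in DAILY_INDEX_COLUMNS[2:-1]:
        out[f"mean_{col}"] = float(valid[col].mean()) if len(valid) else np.nan
    out["adrr"] = adrr(day_rows)
    out["modd"] = modd_val
    return pd.Series(out)


def cohort_daily_table(
    traces: Iterable[GlucoseTrace],
    conga_lag_hours: float = 1.0,
    valid_fraction: float = DEFAULT_VALID_FRACTION,
) -> pd.DataFrame:
    """Stack :func:`daily_indices` over traces, carrying the cohort label."""
    frames = []
    for tr in traces:
        df = daily_indices(tr, conga_lag_hours, valid_fraction)
        df.insert(1, "cohort", tr.cohort)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def cohort_summary_table(
    traces: Iterable[GlucoseTrace],
    conga_lag_hours: float = 1.0,
    valid_fraction: float = DEFAULT_VALID_FRACTION,
) -> pd.DataFrame:
    """Stack :func:`subject_summary` over traces, carrying the cohort label."""
    rows = []
    for tr in traces:
        s = subject_summary(tr, conga_lag_hours, valid_fraction)
        s["cohort"] = tr.cohort
        rows.append(s)
    df = pd.DataFrame(rows)
    cols = ["subject_id", "cohort"] + [c for c in df.columns if c not in ("subject_id", "cohort")]
    return df[cols].reset_index(drop=True)
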