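"""Synthetic two-cohort CGM study generator.

Emulates a 14-day continuous-glucose-monitoring study of healthy and
pre-diabetic adults (15-minute sampling) together with the accompanying
per-subject biomarker panel (HbA1c, 2-h OGTT, HOMA-IR, Hs-CRP, cortisol,
fasting glucose at baseline and study end) and a per-day activity table
(steps, heart rate, sleep).

Glucose model, per subject ``s`` on study day ``d`` at clock time ``t``::

    G = B_s(d) + circadian(t) + sum_meals pulse(t) + AR1_noise(t)

clipped to the sensor range [40, 500] mg/dL, where

* a latent dysglycemia factor ``z_s ~ N(0,1)`` (drawn once per subject)
  shifts the subject's baseline and scales meal-excursion amplitudes,
  and the same factor loads on the biomarker panel — this is what makes
  glycemic variability and HOMA-IR / OGTT / HbA1c / Hs-CRP correlate
  within a cohort;
* ``B_s(d)`` drifts linearly across days (negative drift = improvement
  over the study), anchored at the mid-window day so the drift does not
  move the days 2-14 average;
* meals are three pulses per day (breakfast / lunch / dinner) with
  lognormal amplitudes, a linear rise and an exponential decay; the
  pre-diabetic preset has larger, slower-clearing excursions;
* noise is AR(1) at the grid step (autocorrelated sensor and
  physiological fluctuation), parameterized by its stationary SD.

Default presets for the two cohorts live in ``presets/default.yaml`` and
are calibrated so the pipeline's days 2-14 cohort summaries (mean
glucose, GV by SD and CV, TIR/TAR/TBR, MAGE) match a published
benchmarking study of 53 healthy and 52 pre-diabetic Indian/South Asian
adults.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from cgmetrics.io import GLUCOSE_MAX, GLUCOSE_MIN, GlucoseTrace

#: All simulated traces start at local midnight of this date; the absolute
#: date is arbitrary (analyses only use study-day numbers).
EPOCH = date(2024, 1, 1)


class ConfigError(ValueError):
    """Raised for internally inconsistent simulation configurations."""


@dataclass
class CohortPreset:
    """Archetype parameters for one cohort.

    Glucose-trace parameters are in mg/dL and minutes; ``*_latent_*``
    couplings express how strongly the subject's latent dysglycemia
    factor moves each quantity.  ``biomarkers`` and ``activity`` are flat
    mappings validated against the keys the generator uses.
    """

    name: str
    baseline_mean: float = 95.0
    baseline_sd: float = 10.0
    baseline_latent_weight: float = 0.6  # share of baseline SD carried by z
    day_effect_sd: float = 3.0
    baseline_drift_per_day: float = -0.4  # mg/dL per day, anchored mid-window
    circadian_amp: float = 7.0
    circadian_peak_hour: float = 16.0
    meal_hours: tuple = (8.0, 13.0, 20.0)
    meal_jitter_sd_min: float = 25.0
    meal_amp_median: float = 38.0
    meal_amp_sigma: float = 0.35  # lognormal sigma of pulse amplitude
    meal_rise_min: float = 40.0
    meal_decay_min: float = 70.0
    amp_latent_coupling: float = 0.25  # z coefficient in log amplitude
    amp_drift_per_day: float = -0.01  # relative amplitude change per day
    noise_sd: float = 8.0  # stationary SD of the AR(1) component
    noise_rho: float = 0.8
    biomarker_loading: float = 0.0  # z loading on biomarker panel
    target_r: float = 0.0  # intended r(J-index, biomarker); validation only
    biomarkers: dict = field(default_factory=dict)
    activity: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.noise_rho < 1:
            raise ConfigError("noise_rho must lie in [0, 1)")
        for key in ("baseline_sd", "day_effect_sd", "meal_amp_sigma", "noise_sd",
                    "meal_jitter_sd_min"):
            if getattr(self, key) < 0:
                raise ConfigError(f"{key} must be non-negative")
        if not 0 <= self.baseline_latent_weight <= 1:
            raise ConfigError("baseline_latent_weight must lie in [0, 1]")
        if self.target_r != 0 and self.biomarker_loading == 0:
            raise ConfigError(
                f"{self.name}: target_r={self.target_r} requires a nonzero biomarker_loading"
            )


@dataclass
class SimulationConfig:
    """Full study configuration: cohort sizes, grid, presets, seed."""

    n_healthy: int = 53
    n_prediabetic: int = 52
    days: int = 14
    interval_min: float = 15.0
    healthy: CohortPreset = None
    prediabetic: CohortPreset = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.days < 1 or self.interval_min <= 0:
            raise ConfigError("days must be >= 1 and interval_min > 0")
        if self.n_healthy < 0 or self.n_prediabetic < 0:
            raise ConfigError("cohort sizes must be non-negative")

    def preset(self, cohort: str) -> CohortPreset:
        if cohort == "healthy":
            return self.healthy
        if cohort == "prediabetic":
            return self.prediabetic
        raise ConfigError(f"unknown cohort {cohort!r}")


def _preset_path() -> Path:
    return Path(importlib.resources.files("cgmetrics") / "presets" / "default.yaml")


def load_config(path: Optional[str | Path] = None, rng_seed: Optional[int] = None,
                **overrides) -> SimulationConfig:
    """Load a :class:`SimulationConfig` from YAML (packaged default preset).

    Top-level keys mirror the dataclass fields; ``healthy`` and
    ``prediabetic`` are nested preset mappings.  Keyword overrides
    replace top-level fields.
    """
    raw = yaml.safe_load(Path(path or _preset_path()).read_text())
    raw.update(overrides)
    if rng_seed is not None:
        raw["rng_seed"] = rng_seed
    healthy = CohortPreset(name="healthy", **raw.pop("healthy"))
    pre = CohortPreset(name="prediabetic", **raw.pop("prediabetic"))
    return SimulationConfig(healthy=healthy, prediabetic=pre, **raw)


def default_config(rng_seed: int = 0) -> SimulationConfig:
    """The packaged study configuration (53 healthy + 52 pre-diabetic)."""
    return load_config(rng_seed=rng_seed)


# ---------------------------------------------------------------------------
# glucose traces


def _meal_pulse(minutes_since: np.ndarray, amp: float, rise: float, decay: float) -> np.ndarray:
    """Linear rise to ``amp`` over ``rise`` minutes, exponential decay after."""
    up = amp * minutes_since / rise
    down = amp * np.exp(-(minutes_since - rise) / decay)
    return np.where(minutes_since < 0, 0.0, np.where(minutes_since < rise, up, down))


def simulate_subject(
    config: SimulationConfig,
    cohort: str,
    seed,
    subject_id: Optional[str] = None,
    z: Optional[float] = None,
) -> GlucoseTrace:
    """Simulate one subject's full-study glucose trace.

    Deterministic given ``(config, seed, z)``.  ``z`` is the subject's
    latent dysglycemia factor; if omitted it is drawn from the subject's
    own stream (pass it explicitly to share the factor with the
    biomarker generator).
    """
    preset = config.preset(cohort)
    rng = np.random.default_rng(seed)
    if z is None:
        z = float(rng.standard_normal())
    sid = subject_id or f"{cohort[:1].upper()}000"

    step = config.interval_min
    per_day = int(round(24 * 60 / step))
    n = per_day * config.days
    t_min = np.arange(n) * step  # minutes since study start (midnight day 1)
    hour = (t_min / 60.0) % 24.0
    day = t_min // (24 * 60)  # 0-based
    mid = (config.days - 1) / 2.0  # drift anchor: mid-study day (0-based)

    lam = preset.baseline_latent_weight
    subj_base = preset.baseline_mean + preset.baseline_sd * (
        lam * z + np.sqrt(1 - lam**2) * rng.standard_normal()
    )
    day_effects = rng.normal(0.0, preset.day_effect_sd, config.days)
    baseline = subj_base + preset.baseline_drift_per_day * (day - mid) + day_effects[day.astype(int)]

    circadian = preset.circadian_amp * np.cos(
        2 * np.pi * (hour - preset.circadian_peak_hour) / 24.0
    )

    # per-subject amplitude multiplier from the latent factor (unit mean)
    amp_mult = np.exp(preset.amp_latent_coupling * z - preset.amp_latent_coupling**2 / 2)
    meals = np.zeros(n)
    for d in range(config.days if preset.meal_amp_median > 0 else 0):
        day_amp_factor = max(0.0, 1.0 + preset.amp_drift_per_day * (d - mid))
        for mh in preset.meal_hours:
            start = d * 24 * 60 + mh * 60 + rng.normal(0.0, preset.meal_jitter_sd_min)
            amp = (
                np.exp(np.log(preset.meal_amp_median) + preset.meal_amp_sigma * rng.standard_normal())
                * amp_mult
                * day_amp_factor
            )
            meals += _meal_pulse(t_min - start, amp, preset.meal_rise_min, preset.meal_decay_min)

    rho = preset.noise_rho
    innov = rng.normal(0.0, preset.noise_sd * np.sqrt(1 - rho**2), n)
    noise = np.empty(n)
    noise[0] = rng.normal(0.0, preset.noise_sd)
    for i in range(1, n):
        noise[i] = rho * noise[i - 1] + innov[i]

    glucose = np.clip(baseline + circadian + meals + noise, GLUCOSE_MIN, GLUCOSE_MAX)
    idx = pd.date_range(pd.Timestamp(EPOCH), periods=n, freq=pd.Timedelta(minutes=step))
    return GlucoseTrace(
        subject_id=sid, samples=pd.Series(glucose, index=idx), cohort=cohort,
        interval_min=step, activation_date=EPOCH,
    )


# ---------------------------------------------------------------------------
# biomarkers and activity


def homa_ir(fasting_glucose: float, fasting_insulin: float) -> float:
    """Homeostasis-model insulin-resistance index: glucose * insulin / 405.

    ``fasting_glucose`` in mg/dL, ``fasting_insulin`` in µU/mL; both must
    be strictly positive.
    """
    if fasting_glucose <= 0 or fasting_insulin <= 0:
        raise ValueError("fasting glucose and insulin must be positive")
    return fasting_glucose * fasting_insulin / 405.0


def _corr_normal(rng, mean, sd, lam, z, lo=None, hi=None):
    """Normal draw with z-loading ``lam``; clipped into [lo, hi] if given."""
    x = mean + sd * (lam * z + np.sqrt(max(0.0, 1 - lam**2)) * rng.standard_normal())
    if lo is not None or hi is not None:
        x = float(np.clip(x, lo if lo is not None else -np.inf, hi if hi is not None else np.inf))
    return float(x)


def _corr_lognormal(rng, median, sigma, lam, z):
    return float(
        np.exp(np.log(median) + sigma * (lam * z + np.sqrt(max(0.0, 1 - lam**2)) * rng.standard_normal()))
    )


def _simulate_panel_row(preset: CohortPreset, rng, z: float, subject_id: str) -> dict:
    b = preset.biomarkers
    lam = preset.biomarker_loading
    fbg = _corr_normal(rng, b["fbg_mean"], b["fbg_sd"], lam, z, b["fbg_lo"], b["fbg_hi"])
    hba1c = _corr_normal(rng, b["hba1c_mean"], b["hba1c_sd"], lam, z, b["hba1c_lo"], b["hba1c_hi"])
    ogtt = _corr_normal(rng, b["ogtt_mean"], b["ogtt_sd"], lam, z, b["ogtt_lo"], b["ogtt_hi"])
    insulin = _corr_lognormal(rng, b["insulin_median"], b["insulin_sigma"], lam, z)
    hscrp = _corr_lognormal(rng, b["hscrp_median"], b["hscrp_sigma"], lam, z)
    cortisol = _corr_normal(rng, b["cortisol_mean"], b["cortisol_sd"], 0.0, z, lo=1.0)
    fbg_end = max(
        GLUCOSE_MIN, fbg + b["fbg_end_shift"] + rng.normal(0.0, b["fbg_end_noise_sd"])
    )
    return {
        "subject_id": subject_id,
        "cohort": preset.name,
        "hba1c": round(hba1c, 2),
        "ogtt_2h": round(ogtt, 1),
        "homa_ir": round(homa_ir(fbg, insulin), 3),
        "hscrp": round(hscrp, 3),
        "cortisol": round(cortisol, 2),
        "fbg_baseline": round(fbg, 1),
        "fbg_end": round(fbg_end, 1),
    }


def _simulate_activity_rows(preset: CohortPreset, rng, z: float, subject_id: str, days: int) -> list:
    a = preset.activity
    subj_steps = a["steps_mean"] + a["steps_z_coupling"] * z + rng.normal(0, a["steps_subject_sd"])
    subj_hr = a["hr_mean"] + a["hr_z_coupling"] * z + rng.normal(0, a["hr_subject_sd"])
    subj_sleep = a["sleep_mean"] + a["sleep_z_coupling"] * z + rng.normal(0, a["sleep_subject_sd"])
    rows = []
    for d in range(days):
        rows.append(
            {
                "subject_id": subject_id,
                "date": pd.Timestamp(EPOCH) + pd.Timedelta(days=d),
                "steps": int(max(0, subj_steps + rng.normal(0, a["steps_day_sd"]))),
                "hr_bpm": round(max(35.0, subj_hr + rng.normal(0, a["hr_day_sd"])), 1),
                "sleep_min": round(max(0.0, subj_sleep + rng.normal(0, a["sleep_day_sd"])), 0),
            }
        )
    return rows


def simulate_cohorts(config: SimulationConfig):
    """Simulate the full study.

    Returns ``(traces, panel, activity)``: a list of
    :class:`GlucoseTrace` (one per subject, already on the 15-minute
    grid), the per-subject biomarker panel ``DataFrame``, and the
    per-subject-day activity ``DataFrame``.  Byte-identical outputs for
    identical ``(config, rng_seed)``.
    """
    ss = np.random.SeedSequence(config.rng_seed)
    traces, panel_rows, activity_rows = [], [], []
    plan = [("healthy", "H", config.n_healthy), ("prediabetic", "P", config.n_prediabetic)]
    child_seeds = ss.spawn(sum(n for _, _, n in plan))
    k = 0
    for cohort, prefix, n in plan:
        preset = config.preset(cohort)
        for i in range(n):
            sid = f"{prefix}{i + 1:03d}"
            rng = np.random.default_rng(child_seeds[k])
            k += 1
            z = float(rng.standard_normal())
            traces.append(simulate_subject(config, cohort, child_seeds[k - 1].spawn(1)[0],
                                           subject_id=sid, z=z))
            panel_rows.append(_simulate_panel_row(preset, rng, z, sid))
            activity_rows.append(_simulate_activity_rows(preset, rng, z, sid, config.days))
    panel = pd.DataFrame(panel_rows, columns=[
        "subject_id", "cohort", "hba1c", "ogtt_2h", "homa_ir", "hscrp", "cortisol",
        "fbg_baseline", "fbg_end",
    ])
    activity = pd.DataFrame([r for rows in activity_rows for r in rows])
    if activity.empty:
        activity = pd.DataFrame(columns=["subject_id", "date", "steps", "hr_bpm", "sleep_min"])
    return traces, panel, activity
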