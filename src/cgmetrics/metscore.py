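"""Transparent daily metabolic-score surrogate.

Commercial CGM platforms summarize each day as a 0-100 "metabolic
score" built from glycemic variability, time in a target range, and mean
glucose.  The exact commercial algorithms are proprietary; this module
defines an explicit, documented composite from the same three ingredient
families so the score's behavior can be studied and re-fit:

* ``tir_subscore`` — the percentage of readings in the tight 70-110
  mg/dL target band (rTIR), already on a 0-100 scale;
* ``mean_subscore`` — a clamped linear ramp on the day's mean glucose:
  maximal (100) inside the 70-110 mg/dL band, falling linearly to 0 at
  the configurable outer anchors (defaults 40 and 250 mg/dL);
* ``gv_subscore`` — ``100 * (1 - min(CV / cv_max, 1))`` with ``cv_max``
  defaulting to the 36 % consensus glycemic-stability threshold.

The score is the weighted sum of the three subscores (default weights
0.40 GV, 0.35 rTIR, 0.25 mean), so it is monotone: it never increases
when CV rises or when the mean moves away from the target band, and
never decreases when rTIR rises.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd


@dataclass(frozen=True)
class MetScoreConfig:
    """Weights and anchors of the composite score.

    Weights must be non-negative and sum to 1.  The mean-glucose ramp is
    maximal on [band_lo, band_hi] and reaches 0 at [anchor_lo,
    anchor_hi].
    """

    w_gv: float = 0.40
    w_tir: float = 0.35
    w_mean: float = 0.25
    band_lo: float = 70.0
    band_hi: float = 110.0
    anchor_lo: float = 40.0
    anchor_hi: float = 250.0
    cv_max: float = 36.0

    def __post_init__(self) -> None:
        w = (self.w_gv, self.w_tir, self.w_mean)
        if any(x < 0 for x in w) or abs(sum(w) - 1.0) > 1e-9:
            raise ValueError("weights must be non-negative and sum to 1")
        if not (self.anchor_lo < self.band_lo < self.band_hi < self.anchor_hi):
            raise ValueError("require anchor_lo < band_lo < band_hi < anchor_hi")
        if self.cv_max <= 0:
            raise ValueError("cv_max must be positive")


DEFAULT_METSCORE = MetScoreConfig()


def _mean_subscore(mean: float, cfg: MetScoreConfig) -> float:
    if cfg.band_lo <= mean <= cfg.band_hi:
        return 100.0
    if mean <= cfg.anchor_lo or mean >= cfg.anchor_hi:
        return 0.0
    if mean < cfg.band_lo:
        return 100.0 * (mean - cfg.anchor_lo) / (cfg.band_lo - cfg.anchor_lo)
    return 100.0 * (cfg.anchor_hi - mean) / (cfg.anchor_hi - cfg.band_hi)


def compute_metscore(
    mean_glucose: float,
    cv: float,
    rtir: float,
    config: MetScoreConfig = DEFAULT_METSCORE,
) -> dict:
    """Score one day from its mean glucose (mg/dL), CV (%), and rTIR (%).

    Returns a mapping with ``score`` and the three subscores, all on
    0-100; every field is NaN if any input is missing (undefined day).
    """
    if not (np.isfinite(mean_glucose) and np.isfinite(cv) and np.isfinite(rtir)):
        return {"score": np.nan, "gv_subscore": np.nan, "tir_subscore": np.nan,
                "mean_subscore": np.nan}
    gv_sub = 100.0 * (1.0 - min(max(cv, 0.0) / config.cv_max, 1.0))
    tir_sub = float(np.clip(rtir, 0.0, 100.0))
    mean_sub = _mean_subscore(float(mean_glucose), config)
    score = config.w_gv * gv_sub + config.w_tir * tir_sub + config.w_mean * mean_sub
    return {"score": score, "gv_subscore": gv_sub, "tir_subscore": tir_sub,
            "mean_subscore": mean_sub}


def score_daily_table(daily: pd.DataFrame, config: MetScoreConfig = DEFAULT_METSCORE) -> pd.DataFrame:
    """Score every subject-day of a per-day index table.

    ``daily`` must carry ``subject_id``, ``day_index``, ``mean_glucose``,
    ``cv`` and ``rtir`` columns (the output of the index engine).
    """
    recs = []
    for _, row in daily.iterrows():
        rec = {"subject_id": row["subject_id"], "day_index": row["day_index"]}
        rec.update(compute_metscore(row["mean_glucose"], row["cv"], row["rtir"], config))
        recs.append(rec)
    return pd.DataFrame(
        recs, columns=["subject_id", "day_index", "score", "gv_subscore", "tir_subscore",
                       "mean_subscore"]
    )
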