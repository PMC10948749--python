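"""End-to-end study pipeline: simulate -> indices -> score -> analyze.

Every stage reads and writes only the fixed CSV dialects of
:mod:`cgmetrics.io`, so exported real CGM data can replace the simulator
by pointing ``input_dir`` at a directory containing ``traces.csv``,
``panel.csv`` and ``activity.csv``.

Output layout under ``out_dir``::

    traces.csv            raw (simulated or copied) glucose traces
    panel.csv             per-subject biomarker panel
    activity.csv          per-subject-day activity table
    daily_indices.csv     per subject-day glycemic indices (days 2-14)
    subject_summary.csv   per-subject cross-day aggregates (ADRR, MODD, means)
    metscore_daily.csv    per subject-day composite metabolic score
    metscore_weights.json score weights/anchors sidecar
    endpoints_by_day.csv  cohort x day least-squares means, CIs, and the
                          two-factor p-values for each primary endpoint
    index_biomarker_correlations.csv   per-cohort index x biomarker/activity grid
    metscore_correlations.csv          per-cohort score x biomarker/activity grid
    roc_auc.csv           per-index cohort-separation AUC
    fbg_ancova.csv        baseline-adjusted fasting-glucose comparison
    report.json           run metadata, table paths, headline summary
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import pandas as pd

from cgmetrics import indices as gv
from cgmetrics import io as cio
from cgmetrics.metscore import MetScoreConfig, score_daily_table
from cgmetrics.simulate import SimulationConfig, default_config, load_config, simulate_cohorts
from cgmetrics.stats import ancova_endpoint, compare_groups_over_days, correlation_grid, roc_separation

logger = logging.getLogger(__name__)

PRIMARY_ENDPOINTS = ["mean_glucose", "tir", "rtir", "tar", "tbr", "sd", "cv", "mage"]
SUMMARY_INDEX_COLS = [
    "mean_j_index",
    "mean_hbgi",
    "mean_lbgi",
    "adrr",
    "mean_mage",
    "modd",
    "mean_conga_n",
]
BIOMARKER_COLS = ["hba1c", "ogtt_2h", "homa_ir", "hscrp", "cortisol"]
ACTIVITY_COLS = ["steps", "hr_bpm", "sleep_min"]


def config_hash(config: SimulationConfig) -> str:
    """Deterministic hash of a simulation configuration."""
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_inputs(input_dir: Path):
    traces = cio.read_trace_csv(input_dir / "traces.csv")
    panel = cio.read_panel_csv(input_dir / "panel.csv")
    activity = cio.read_activity_csv(input_dir / "activity.csv")
    cohort_of = dict(zip(panel["subject_id"], panel["cohort"]))
    for tr in traces:
        tr.cohort = cohort_of.get(tr.subject_id)
    return traces, panel, activity


def run_pipeline(
    config: Optional[SimulationConfig | str | Path] = None,
    out_dir: str | Path = "cgmetrics_out",
    seed: Optional[int] = None,
    input_dir: Optional[str | Path] = None,
    conga_lag_hours: float = 1.0,
    metscore_config: MetScoreConfig = MetScoreConfig(),
    start_day: int = 2,
    end_day: int = 14,
) -> dict:
    """Run the full study pipeline and return the analysis report.

    ``config`` may be a :class:`SimulationConfig`, a YAML path, or None
    (packaged default).  ``seed`` overrides the config's ``rng_seed``.
    With ``input_dir`` the simulation stage is skipped and user CSVs are
    analyzed instead.  On any stage failure a ``FAILED`` marker naming
    the stage is left in ``out_dir`` and the exception propagates.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if isinstance(config, (str, Path)):
        config = load_config(config, rng_seed=seed)
    elif config is None:
        config = default_config(rng_seed=seed or 0)
    elif seed is not None:
        config = dataclasses.replace(config, rng_seed=seed)

    stage = "setup"
    try:
        stage = "simulate"
        if input_dir is not None:
            traces, panel, activity = _load_inputs(Path(input_dir))
            logger.info("loaded %d traces from %s", len(traces), input_dir)
        else:
            traces, panel, activity = simulate_cohorts(config)
            logger.info(
                "simulated %d subjects (%d healthy, %d pre-diabetic), seed=%d",
                len(traces), config.n_healthy, config.n_prediabetic, config.rng_seed,
            )
        cio.write_trace_csv(traces, out / "traces.csv")
        cio.write_panel_csv(panel, out / "panel.csv")
        cio.write_activity_csv(activity, out / "activity.csv")

        stage = "indices"
        end_day = min(end_day, config.days if input_dir is None else end_day)
        windowed = []
        for tr in traces:
            g = cio.resample_to_grid(tr, config.interval_min)
            windowed.append(cio.analysis_window(g, start_day, end_day,
                                                activation_date=g.start.date()))
        daily = gv.cohort_daily_table(windowed, conga_lag_hours)
        summary = gv.cohort_summary_table(windowed, conga_lag_hours)
        daily[gv.DAILY_INDEX_COLUMNS + ["cohort", "valid"]].to_csv(
            out / "daily_indices.csv", index=False, lineterminator="\n")
        summary.to_csv(out / "subject_summary.csv", index=False, lineterminator="\n")
        logger.info("indices: %d subject-days, %d subjects", len(daily), len(summary))

        stage = "score"
        scored = score_daily_table(daily[daily["valid"]], metscore_config)
        scored.to_csv(out / "metscore_daily.csv", index=False, lineterminator="\n")
        (out / "metscore_weights.json").write_text(
            json.dumps(dataclasses.asdict(metscore_config), indent=2) + "\n")

        stage = "analyze"
        tables = _analyze(daily, summary, scored, panel, activity, out)

        stage = "report"
        report = {
            "config_hash": config_hash(config),
            "seed": config.rng_seed,
            "timestamp": datetime.now(timezone.utc).isoformat(),
            "n_subjects": len(traces),
            "tables": {k: str(v) for k, v in tables.items()},
            "headline": _headline(daily, tables),
        }
        (out / "report.json").write_text(json.dumps(report, indent=2) + "\n")
        return report
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        logger.error("pipeline failed at stage %s: %s", stage, exc)
        raise


def _subject_level(panel: pd.DataFrame, activity: pd.DataFrame) -> pd.DataFrame:
    """Merge biomarkers with per-subject activity means."""
    act = activity.groupby("subject_id")[ACTIVITY_COLS].mean().reset_index()
    return panel.merge(act, on="subject_id", how="left")


def _analyze(daily, summary, scored, panel, activity, out: Path) -> dict:
    tables = {}
    valid = daily[daily["valid"]]

    # endpoint x day x cohort comparisons (Fig. 2-style)
    rows = []
    for ep in PRIMARY_ENDPOINTS:
        res = compare_groups_over_days(valid, endpoint=ep)
        lsm = res.lsm.copy()
        lsm.insert(0, "endpoint", ep)
        lsm["p_cohort"] = res.p_cohort
        lsm["p_day"] = res.p_day
        lsm["p_interaction"] = res.p_interaction
        rows.append(lsm)
    pd.concat(rows, ignore_index=True).to_csv(
        out / "endpoints_by_day.csv", index=False, lineterminator="\n")
    tables["endpoints_by_day"] = out / "endpoints_by_day.csv"

    # per-cohort index x biomarker correlation grids (Table 1-style)
    subj = _subject_level(panel, activity)
    grids = []
    for cohort, grp in subj.groupby("cohort"):
        idx = summary[summary["cohort"] == cohort][["subject_id"] + SUMMARY_INDEX_COLS]
        grids.append(
            correlation_grid(idx, grp[["subject_id"] + BIOMARKER_COLS + ACTIVITY_COLS],
                             cohort=cohort)
        )
    pd.concat(grids, ignore_index=True).to_csv(
        out / "index_biomarker_correlations.csv", index=False, lineterminator="\n")
    tables["index_biomarker_correlations"] = out / "index_biomarker_correlations.csv"

    # metabolic score x biomarker correlations (Table 2-style)
    mean_score = scored.groupby("subject_id", as_index=False)["score"].mean()
    sgrids = []
    for cohort, grp in subj.groupby("cohort"):
        ms = mean_score[mean_score["subject_id"].isin(grp["subject_id"])]
        cols = BIOMARKER_COLS + ["fbg_baseline"] + ACTIVITY_COLS
        sgrids.append(correlation_grid(ms, grp[["subject_id"] + cols], cohort=cohort))
    pd.concat(sgrids, ignore_index=True).to_csv(
        out / "metscore_correlations.csv", index=False, lineterminator="\n")
    tables["metscore_correlations"] = out / "metscore_correlations.csv"

    # ROC separation per cross-day index
    roc_rows = []
    for col in SUMMARY_INDEX_COLS + ["mean_mean_glucose", "mean_sd"]:
        res = roc_separation(summary[col], summary["cohort"])
        roc_rows.append({"index": col, "auc": res.auc, "positive_cohort": res.positive_cohort})
    pd.DataFrame(roc_rows).to_csv(out / "roc_auc.csv", index=False, lineterminator="\n")
    tables["roc_auc"] = out / "roc_auc.csv"

    # baseline-adjusted fasting-glucose endpoint (ANCOVA)
    anc = ancova_endpoint(panel["fbg_end"], panel["fbg_baseline"], panel["cohort"])
    pd.DataFrame([dataclasses.asdict(anc)]).to_csv(
        out / "fbg_ancova.csv", index=False, lineterminator="\n")
    tables["fbg_ancova"] = out / "fbg_ancova.csv"
    return tables


def _headline(daily: pd.DataFrame, tables: dict) -> dict:
    valid = daily[daily["valid"]]
    per_cohort = valid.groupby("cohort")[PRIMARY_ENDPOINTS].mean().round(2)
    corr = pd.read_csv(tables["index_biomarker_correlations"])
    corr = corr[corr["variable"].isin(["hba1c", "ogtt_2h", "homa_ir"])].dropna(subset=["r"])
    strongest = (
        corr.loc[corr.groupby("cohort")["r"].idxmax()]
        [["cohort", "index", "variable", "r", "p_value"]]
        .round({"r": 3, "p_value": 4})
    )
    return {
        "cohort_endpoint_means": per_cohort.to_dict(orient="index"),
        "strongest_positive_correlation": strongest.to_dict(orient="records"),
    }
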