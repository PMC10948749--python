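"""Cohort-comparison and correlation statistics.

The statistical conventions used throughout:

* one-pass outlier removal: mean ± 3 SD for normally distributed
  vectors, Q1 − 3·IQR / Q3 + 3·IQR (type-7 linear-interpolation
  quantiles) otherwise;
* a Shapiro-Wilk normality gate at α = 0.05 on each variable chooses
  Pearson (both pass) or Spearman (otherwise) correlation;
* group × day comparison is a two-factor fixed-effect linear model with
  interaction (day categorical), reporting type-II main-effect and
  interaction p-values plus per-cohort per-day least-squares means with
  95 % CIs;
* baseline-adjusted endpoint comparison is ANCOVA
  (``end ~ cohort + baseline``);
* cohort separation of an index is the empirical ROC AUC, oriented so
  that the cohort with the higher index mean is the positive class.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from sklearn.metrics import roc_auc_score, roc_curve
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# outliers


def remove_outliers(values: Sequence[float], distribution: str = "normal"):
    """One-pass outlier filter.

    ``distribution="normal"`` drops values outside mean ± 3 SD;
    ``"nonparametric"`` drops values below Q1 − 3·IQR or above Q3 +
    3·IQR (linear-interpolation quantiles).  Vectors with fewer than 4
    values pass through unchanged with a warning.

    Returns ``(kept_values, n_removed)``.
    """
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 4:
        logger.warning("remove_outliers: %d value(s) < 4, passing through", vals.size)
        return vals, 0
    if distribution == "normal":
        mu, sd = vals.mean(), vals.std(ddof=1)
        keep = (vals >= mu - 3 * sd) & (vals <= mu + 3 * sd)
    elif distribution == "nonparametric":
        q1, q3 = np.quantile(vals, [0.25, 0.75])  # type-7 linear interpolation
        iqr = q3 - q1
        keep = (vals >= q1 - 3 * iqr) & (vals <= q3 + 3 * iqr)
    else:
        raise ValueError("distribution must be 'normal' or 'nonparametric'")
    return vals[keep], int((~keep).sum())


# ---------------------------------------------------------------------------
# correlation


@dataclass
class CorrelationResult:
    """Normality-gated correlation between two paired vectors."""

    method: str  # "pearson" or "spearman"
    r: float
    p_value: float
    n_used: int
    variable_pair: Optional[tuple] = None
    cohort: Optional[str] = None


def correlate(
    x: Sequence[float],
    y: Sequence[float],
    alpha: float = 0.05,
    variable_pair: Optional[tuple] = None,
    cohort: Optional[str] = None,
) -> CorrelationResult:
    """Correlate two paired vectors with a Shapiro-Wilk normality gate.

    Pearson is used when both variables pass Shapiro-Wilk at ``alpha``;
    Spearman otherwise.  Incomplete pairs are dropped; requires at least
    5 complete pairs.  Zero variance in either vector yields an
    undefined result (``r = p = NaN``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = int(x.size)
    if n < 5:
        raise ValueError(f"need >= 5 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult("undefined", np.nan, np.nan, n, variable_pair, cohort)
    normal = sps.shapiro(x).pvalue > alpha and sps.shapiro(y).pvalue > alpha
    if normal:
        r, p = sps.pearsonr(x, y)
        method = "pearson"
    else:
        r, p = sps.spearmanr(x, y)
        method = "spearman"
    return CorrelationResult(method, float(r), float(p), n, variable_pair, cohort)


def correlation_grid(
    left: pd.DataFrame,
    right: pd.DataFrame,
    key: str = "subject_id",
    cohort: Optional[str] = None,
    adjust: bool = False,
) -> pd.DataFrame:
    """All pairwise correlations between the numeric columns of two tables.

    ``left`` and ``right`` are merged on ``key``; every (left column,
    right column) pair is correlated with :func:`correlate`.  With
    ``adjust=True`` a Benjamini-Hochberg adjusted p column is appended
    (the default presentation is unadjusted).
    """
    merged = left.merge(right, on=key, suffixes=("_x", "_y"))
    lcols = [c for c in left.columns if c != key and np.issubdtype(left[c].dtype, np.number)]
    rcols = [c for c in right.columns if c != key and np.issubdtype(right[c].dtype, np.number)]
    rows = []
    for lc in lcols:
        for rc in rcols:
            lx = lc if lc in merged.columns else f"{lc}_x"
            rx = rc if rc in merged.columns else f"{rc}_y"
            res = correlate(merged[lx], merged[rx], variable_pair=(lc, rc), cohort=cohort)
            rows.append(
                {
                    "index": lc,
                    "variable": rc,
                    "cohort": cohort,
                    "method": res.method,
                    "r": res.r,
                    "p_value": res.p_value,
                    "n_used": res.n_used,
                }
            )
    out = pd.DataFrame(rows)
    if adjust and len(out):
        ok = out["p_value"].notna()
        adj = np.full(len(out), np.nan)
        if ok.any():
            adj[ok.to_numpy()] = multipletests(out.loc[ok, "p_value"], method="fdr_bh")[1]
        out["p_adjusted"] = adj
    return out


# ---------------------------------------------------------------------------
# group x day comparison


@dataclass
class GroupComparisonResult:
    """Two-factor (cohort × day) comparison of one per-day endpoint."""

    endpoint: str
    p_cohort: float
    p_day: float
    p_interaction: float
    lsm: pd.DataFrame  # columns: cohort, day_index, lsm, ci_lo, ci_hi, n


def compare_groups_over_days(
    table: pd.DataFrame,
    endpoint: str = "value",
    cohort_col: str = "cohort",
    day_col: str = "day_index",
) -> GroupComparisonResult:
    """Two-way fixed-effect comparison of a per-day endpoint across cohorts.

    ``table`` holds one row per subject-day with the endpoint value, the
    cohort label, and the (categorical) study day.  Fits
    ``value ~ C(cohort) * C(day)`` on complete cases, reports type-II
    main-effect and interaction p-values, and per-cell least-squares
    means with 95 % CIs based on the model residual variance.
    """
    df = table[[endpoint, cohort_col, day_col]].dropna().copy()
    df.columns = ["value", "cohort", "day"]
    cohorts = sorted(df["cohort"].unique())
    if len(cohorts) != 2:
        raise ValueError(f"need exactly 2 cohorts, got {cohorts}")
    if df["day"].nunique() < 2:
        raise ValueError("need >= 2 study days")
    if (df.groupby("cohort")["value"].count() < 3).any():
        raise ValueError("need >= 3 observations per cohort")
    model = smf.ols("value ~ C(cohort) * C(day)", data=df).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    p_cohort = float(aov.loc["C(cohort)", "PR(>F)"])
    p_day = float(aov.loc["C(day)", "PR(>F)"])
    p_int = float(aov.loc["C(cohort):C(day)", "PR(>F)"])
    # least-squares means: with a saturated two-factor model these are the
    # cell means; CI from the pooled residual variance
    mse = model.mse_resid
    tcrit = sps.t.ppf(0.975, model.df_resid)
    cells = df.groupby(["cohort", "day"])["value"].agg(["mean", "count"]).reset_index()
    half = tcrit * np.sqrt(mse / cells["count"])
    lsm = pd.DataFrame(
        {
            "cohort": cells["cohort"],
            "day_index": cells["day"],
            "lsm": cells["mean"],
            "ci_lo": cells["mean"] - half,
            "ci_hi": cells["mean"] + half,
            "n": cells["count"],
        }
    )
    return GroupComparisonResult(endpoint, p_cohort, p_day, p_int, lsm)


# ---------------------------------------------------------------------------
# baseline-adjusted endpoint (ANCOVA)


@dataclass
class AncovaResult:
    effect: float  # adjusted cohort effect (second cohort minus first)
    ci_lo: float
    ci_hi: float
    p_value: float
    adjusted: bool  # False when the baseline was constant (plain comparison)


def ancova_endpoint(
    end_values: Sequence[float],
    baseline_values: Sequence[float],
    cohort_labels: Sequence[str],
) -> AncovaResult:
    """Baseline-adjusted two-cohort endpoint comparison.

    Fits ``end ~ cohort + baseline`` and reports the adjusted cohort
    effect with a 95 % CI.  A constant baseline cannot adjust anything,
    so the model falls back to a plain two-group linear comparison with
    a warning.
    """
    df = pd.DataFrame(
        {"end": np.asarray(end_values, float), "base": np.asarray(baseline_values, float),
         "cohort": list(cohort_labels)}
    ).dropna()
    if df["cohort"].nunique() != 2:
        raise ValueError("need exactly two cohorts")
    adjusted = np.ptp(df["base"].to_numpy()) > 0
    formula = "end ~ C(cohort) + base" if adjusted else "end ~ C(cohort)"
    if not adjusted:
        logger.warning("ancova_endpoint: constant baseline; plain two-group comparison")
    model = smf.ols(formula, data=df).fit()
    term = [t for t in model.params.index if t.startswith("C(cohort)")][0]
    ci = model.conf_int().loc[term]
    return AncovaResult(
        effect=float(model.params[term]),
        ci_lo=float(ci[0]),
        ci_hi=float(ci[1]),
        p_value=float(model.pvalues[term]),
        adjusted=adjusted,
    )


# ---------------------------------------------------------------------------
# ROC separation


@dataclass
class RocResult:
    auc: float
    positive_cohort: str  # cohort treated as the positive class
    curve: pd.DataFrame  # columns: fpr, tpr, threshold


def roc_separation(
    values: Sequence[float],
    cohort_labels: Sequence[str],
    positive: str = "prediabetic",
) -> RocResult:
    """Empirical ROC of classifying the positive cohort by an index.

    Orientation is fixed so that the classifier scores in the direction
    of the positive cohort's mean: when the positive cohort has the
    lower index mean the index is negated before the curve is built, so
    the AUC is always >= the separation a random guess achieves on the
    oriented index.
    """
    vals = np.asarray(values, dtype=float)
    labels = np.asarray(list(cohort_labels))
    ok = np.isfinite(vals)
    vals, labels = vals[ok], labels[ok]
    uniq = set(labels)
    if positive not in uniq or len(uniq) != 2:
        raise ValueError("both cohorts must be represented, including the positive one")
    y = (labels == positive).astype(int)
    if vals[y == 1].mean() < vals[y == 0].mean():
        vals = -vals
    fpr, tpr, thr = roc_curve(y, vals)
    return RocResult(
        auc=float(roc_auc_score(y, vals)),
        positive_cohort=positive,
        curve=pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}),
    )
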