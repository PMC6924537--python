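"""Statistical stage: outlier screening, group contrasts, drug-effect models.

The disease effect is assessed by two-sample t-tests of graph measures
between controls and the patient placebo session (hub measures against the
evaluation half of the controls only, so hub definition and hub evaluation
never share subjects).  Drug effects use the crossover structure: the
within-subject difference drug - placebo is regressed on one clinical
covariate at a time (plasma concentration, disease severity, medication
dose, cognitive change, age).  For a two-level within-subject factor this
difference-score regression is algebraically the factor-by-covariate
interaction of a repeated-measures ANOVA.  No multiple-comparison correction
is applied - network measures are not independent - and reports say so.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import SubjectRecord
from .metrics import MetricsRecord

logger = logging.getLogger(__name__)

__all__ = [
    "COVARIATES",
    "DEFAULT_REPORT_METRICS",
    "RegressionResult",
    "TTestResult",
    "build_study_table",
    "remove_outliers",
    "two_sample_ttest",
    "two_sample_ttest_from_stats",
    "paired_drug_contrast",
    "covariate_regression",
    "disease_effect_report",
]

COVARIATES = (
    "age_years",
    "updrs_iii",
    "led_mg_day",
    "plasma_ng_ml",
    "delta_category_fluency",
    "delta_ssrt_ms",
)

#: the design's headline comparisons: clustering and the four hub metrics,
#: plus path length and modularity
DEFAULT_REPORT_METRICS = (
    "clustering",
    "hub_degree",
    "hub_betweenness",
    "hub_closeness",
    "hub_eigen_centrality",
    "path_length",
    "modularity_q",
)

_GLOBAL = ("clustering", "path_length", "modularity_q")


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    variant: str


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p: float
    ci_low: float
    ci_high: float
    n: int


# ---------------------------------------------------------------------------


def build_study_table(
    records: list[SubjectRecord], metric_rows: list[dict]
) -> pd.DataFrame:
    """Long-format study table joining graph measures to clinical covariates.

    ``metric_rows`` are ``MetricsRecord.to_row()`` dicts.  One output row per
    subject-session-metric; patient rows carry the within-subject change in
    the cognitive scores relative to placebo (``delta_category_fluency``,
    ``delta_ssrt_ms``).
    """
    rec_df = pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "group": r.group,
                "session": r.session,
                "age_years": r.age_years,
                "updrs_iii": r.updrs_iii,
                "led_mg_day": r.led_mg_day,
                "plasma_ng_ml": r.plasma_ng_ml,
                "category_fluency": r.category_fluency,
                "ssrt_ms": r.ssrt_ms,
            }
            for r in records
        ]
    )
    placebo = (
        rec_df[rec_df.session == "placebo"]
        .set_index("subject_id")[["category_fluency", "ssrt_ms"]]
        .rename(columns=lambda c: f"placebo_{c}")
    )
    rec_df = rec_df.join(placebo, on="subject_id")
    rec_df["delta_category_fluency"] = rec_df.category_fluency - rec_df.placebo_category_fluency
    rec_df["delta_ssrt_ms"] = rec_df.ssrt_ms - rec_df.placebo_ssrt_ms

    met_df = pd.DataFrame(metric_rows)
    id_cols = ["subject_id", "session", "density"]
    value_cols = [c for c in met_df.columns if c not in id_cols]
    long = met_df.melt(id_vars=id_cols, value_vars=value_cols, var_name="metric")
    cov_cols = [
        "subject_id",
        "session",
        "group",
        "age_years",
        "updrs_iii",
        "led_mg_day",
        "plasma_ng_ml",
        "delta_category_fluency",
        "delta_ssrt_ms",
    ]
    out = long.merge(rec_df[cov_cols], on=["subject_id", "session"], how="left")
    return out


def remove_outliers(values, k: float = 2.0) -> tuple[pd.Series, list]:
    """Drop values more than ``k`` SD from the mean (single pass).

    Mean and SD include every candidate; returns (kept, removed ids).
    """
    vals = pd.Series(values, dtype=float).dropna()
    if len(vals) < 3:
        raise ValueError("need at least 3 values for outlier screening")
    sd = vals.std(ddof=1)
    if sd == 0:
        return vals, []
    z = (vals - vals.mean()).abs() / sd
    removed = list(vals.index[z > k])
    return vals[z <= k], removed


def two_sample_ttest(a, b, variant: str = "welch") -> TTestResult:
    """Two-sample t-test (two-tailed); Welch by default, pooled optional."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if variant not in ("welch", "pooled"):
        raise ValueError(f"variant must be welch|pooled, got {variant!r}")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        equal = np.isclose(a.mean(), b.mean())
        df = len(a) + len(b) - 2
        return TTestResult(0.0 if equal else np.inf, df, 1.0 if equal else 0.0, variant)
    res = sps.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return TTestResult(float(res.statistic), float(res.df), float(res.pvalue), variant)


def two_sample_ttest_from_stats(
    mean1: float,
    sd1: float,
    n1: int,
    mean2: float,
    sd2: float,
    n2: int,
    variant: str = "welch",
) -> TTestResult:
    """Two-sample t-test from summary statistics (mean, SD, n per group)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    res = sps.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=(variant == "pooled")
    )
    if variant == "pooled":
        df = n1 + n2 - 2
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return TTestResult(float(res.statistic), float(df), float(res.pvalue), variant)


def paired_drug_contrast(table: pd.DataFrame, metric: str, drug: str) -> pd.Series:
    """Within-patient difference drug - placebo for one metric.

    Patients missing either session are dropped with a log entry.  The input
    is the long-format study table (or any frame with subject_id, session,
    metric, value columns).
    """
    if drug not in ("atomoxetine", "citalopram"):
        raise ValueError(f"drug must be atomoxetine|citalopram, got {drug!r}")
    sub = table[(table.metric == metric) & (table.group == "patient")]
    wide = sub.pivot_table(index="subject_id", columns="session", values="value", aggfunc="first")
    for needed in ("placebo", drug):
        if needed not in wide.columns:
            wide[needed] = np.nan
    complete = wide[["placebo", drug]].dropna()
    dropped = sorted(set(wide.index) - set(complete.index))
    if dropped:
        logger.info(
            "paired_drug_contrast(%s, %s): dropped %d patient(s) missing a session: %s",
            metric,
            drug,
            len(dropped),
            ", ".join(dropped),
        )
    if complete.empty:
        raise ValueError(f"no complete placebo/{drug} pairs for metric {metric!r}")
    return complete[drug] - complete["placebo"]


def covariate_regression(y, x, alpha: float = 0.05) -> RegressionResult:
    """OLS of a (difference-score) outcome on one covariate.

    Returns slope, intercept, r-squared (squared Pearson correlation),
    two-tailed p for the slope, and its (1 - alpha) confidence interval.
    """
    y = pd.Series(y, dtype=float)
    x = pd.Series(x, dtype=float)
    if len(y) != len(x):
        # align on shared index when both are labelled
        joined = pd.concat([y.rename("y"), x.rename("x")], axis=1, join="inner")
        y, x = joined["y"], joined["x"]
    keep = ~(y.isna() | x.isna())
    y, x = y[keep].to_numpy(), x[keep].to_numpy()
    if len(y) < 4:
        raise ValueError(f"need at least 4 complete cases, got {len(y)}")
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant")
    res = sps.linregress(x, y)
    n = len(y)
    tcrit = sps.t.ppf(1 - alpha / 2, n - 2)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p=float(res.pvalue),
        ci_low=float(res.slope - tcrit * res.stderr),
        ci_high=float(res.slope + tcrit * res.stderr),
        n=n,
    )


def disease_effect_report(
    controls_eval: pd.DataFrame,
    patients_placebo: pd.DataFrame,
    metrics: tuple[str, ...] = DEFAULT_REPORT_METRICS,
    controls_all: pd.DataFrame | None = None,
    outlier_k: float = 2.0,
    variant: str = "welch",
) -> pd.DataFrame:
    """Control-versus-patient comparison table.

    Hub metrics use the evaluation half of the controls only; global metrics
    use the full control group when ``controls_all`` is given.  Outliers
    beyond ``outlier_k`` SD are removed within each group first.  The result
    carries a ``correction`` column stating that no multiple-comparison
    correction was applied (network measures are not independent).
    """
    if controls_eval.empty or patients_placebo.empty:
        raise ValueError("both groups must be non-empty")
    rows = []
    for metric in metrics:
        ctrl_src = controls_all if (metric in _GLOBAL and controls_all is not None) else controls_eval
        ctrl = ctrl_src[ctrl_src.metric == metric].set_index("subject_id")["value"]
        pat = patients_placebo[patients_placebo.metric == metric].set_index("subject_id")["value"]
        # outlier screening needs >= 3 values; tiny groups pass through
        ctrl_kept, ctrl_rm = (
            remove_outliers(ctrl, k=outlier_k) if len(ctrl) >= 3 else (ctrl, [])
        )
        pat_kept, pat_rm = (
            remove_outliers(pat, k=outlier_k) if len(pat) >= 3 else (pat, [])
        )
        tt = two_sample_ttest(ctrl_kept, pat_kept, variant=variant)
        diff = pat_kept.mean() - ctrl_kept.mean()
        rows.append(
            {
                "metric": metric,
                "control_source": "all_controls"
                if (metric in _GLOBAL and controls_all is not None)
                else "evaluation_half",
                "n_controls": len(ctrl_kept),
                "n_patients": len(pat_kept),
                "n_outliers_removed": len(ctrl_rm) + len(pat_rm),
                "control_mean": ctrl_kept.mean(),
                "patient_mean": pat_kept.mean(),
                "direction": "patients_lower"
                if diff < 0
                else ("patients_higher" if diff > 0 else "equal"),
                "t": tt.t,
                "df": tt.df,
                "p": tt.p,
                "correction": "none (network measures are not independent)",
            }
        )
    return pd.DataFrame(rows)
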