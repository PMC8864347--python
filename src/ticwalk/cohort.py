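"""Group-level statistics of the fractal dimension.

Operates on a *cohort table*: one row per session per rater with the fitted
D_f, its goodness of fit, the tic count, and (when available) the latent or
clinical severity score. Provides the change-score correlation between
severity and D_f, per-condition means with confidence intervals, a one-way
within-subjects (repeated measures) ANOVA across suppression conditions, and
paired inter-rater agreement.

Sessions whose fit was degenerate (walker without usable spatial extent) are
excluded from every statistic and counted in the result objects. Reported
p-values are descriptive; no multiplicity correction is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.anova import AnovaRM

from .errors import InsufficientDataError
from .session_io import Condition, Visit
from .spectral import SpectralSettings, CalibrationRecord, estimate_df

__all__ = [
    "build_cohort_table",
    "DeltaResult",
    "delta_analysis",
    "condition_summary",
    "AnovaResult",
    "rm_anova",
    "interrater_agreement",
]

TABLE_COLUMNS = ["subject_id", "visit", "condition", "rater_id",
                 "D_f", "fit_r2", "n_tics", "degenerate", "severity"]


def build_cohort_table(series_list, settings: SpectralSettings,
                       calibration: CalibrationRecord,
                       severity: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Run the D_f pipeline over sessions and join per-visit severity.

    ``severity``, if given, is a frame with columns subject_id / visit /
    severity (as produced by the cohort generator).
    """
    rows = []
    for s in series_list:
        est = estimate_df(s, settings, calibration)
        rows.append((s.subject_id, s.visit.value, s.condition.value,
                     s.rater_id, est.D_f, est.fit_r2, s.n_events,
                     est.degenerate, np.nan))
    table = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    if severity is not None:
        table = table.drop(columns="severity").merge(
            severity, on=["subject_id", "visit"], how="left")
    return table


def _usable(table: pd.DataFrame) -> pd.DataFrame:
    if "degenerate" in table.columns:
        return table[~table["degenerate"].astype(bool)]
    return table


@dataclass
class DeltaResult:
    """Per-subject change scores and their correlation."""

    table: pd.DataFrame  # subject_id, delta_D_f, delta_severity
    r: float
    p: float
    n: int
    n_excluded: int
    flag: Optional[str] = None


def delta_analysis(table: pd.DataFrame) -> DeltaResult:
    """Correlate the 12-month change in D_f with the change in severity.

    Uses baseline-condition sessions only. Each complete subject contributes
    delta_D_f = D_f(12-month) - D_f(screening) and the analogous severity
    change; the Pearson product-moment r and its two-sided t-test p-value
    (n - 2 df) are returned. If either change score has zero variance the
    correlation is undefined and flagged rather than computed.
    """
    base = _usable(table)
    base = base[base["condition"] == Condition.BASELINE.value]
    n_excluded = len(table) - len(_usable(table))
    piv_d = base.pivot_table(index="subject_id", columns="visit",
                             values="D_f", aggfunc="mean")
    piv_s = base.pivot_table(index="subject_id", columns="visit",
                             values="severity", aggfunc="mean")
    for piv in (piv_d, piv_s):
        for col in (Visit.SCREENING.value, Visit.TWELVE_MONTH.value):
            if col not in piv.columns:
                raise InsufficientDataError(
                    f"no baseline-condition rows for visit {col!r}")
    merged = pd.DataFrame({
        "delta_D_f": piv_d[Visit.TWELVE_MONTH.value] - piv_d[Visit.SCREENING.value],
        "delta_severity": piv_s[Visit.TWELVE_MONTH.value] - piv_s[Visit.SCREENING.value],
    }).dropna()
    if len(merged) < 3:
        raise InsufficientDataError(
            f"need >= 3 subjects with both visits, got {len(merged)}")
    merged = merged.reset_index()
    if np.ptp(merged["delta_severity"]) == 0 or np.ptp(merged["delta_D_f"]) == 0:
        return DeltaResult(table=merged, r=np.nan, p=np.nan, n=len(merged),
                           n_excluded=n_excluded,
                           flag="zero variance in a change score")
    r, p = stats.pearsonr(merged["delta_D_f"], merged["delta_severity"])
    return DeltaResult(table=merged, r=float(r), p=float(p), n=len(merged),
                       n_excluded=n_excluded)


def condition_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Mean D_f per (visit, condition) with a t-based 95% confidence interval.

    Singleton cells get NaN interval bounds and a flag instead of an error.
    """
    rows = []
    for (visit, cond), grp in _usable(table).groupby(["visit", "condition"],
                                                     sort=True):
        vals = grp["D_f"].to_numpy(dtype=float)
        n = vals.size
        mean = float(np.mean(vals))
        if n < 2:
            rows.append((visit, cond, n, mean, np.nan, np.nan, "singleton"))
            continue
        sem = float(np.std(vals, ddof=1) / np.sqrt(n))
        half = float(stats.t.ppf(0.975, n - 1) * sem)
        rows.append((visit, cond, n, mean, mean - half, mean + half, None))
    return pd.DataFrame(rows, columns=["visit", "condition", "n", "mean_D_f",
                                       "ci_lo", "ci_hi", "flag"])


@dataclass
class AnovaResult:
    F: float
    df_num: int
    df_den: int
    p: float
    n_subjects: int
    n_conditions: int
    n_dropped_subjects: int


def rm_anova(table: pd.DataFrame, visit: Optional[Visit] = None,
             rater_id: Optional[str] = None) -> AnovaResult:
    """One-way within-subjects ANOVA of D_f across suppression conditions.

    Subjects missing any condition are dropped (with a warning). The F ratio
    is MS_condition / MS_error with the subject effect removed, on
    (k - 1, (n - 1)(k - 1)) degrees of freedom.
    """
    df = _usable(table).copy()
    if visit is not None:
        df = df[df["visit"] == Visit(visit).value]
    if rater_id is not None:
        df = df[df["rater_id"] == rater_id]
    df = (df.groupby(["subject_id", "condition"], as_index=False)["D_f"]
            .mean())
    conds = sorted(df["condition"].unique())
    if len(conds) < 2:
        raise InsufficientDataError(
            f"need >= 2 conditions, got {len(conds)}")
    counts = df.groupby("subject_id")["condition"].nunique()
    complete = counts[counts == len(conds)].index
    n_dropped = int((counts != len(conds)).sum())
    if n_dropped:
        warnings.warn(f"dropping {n_dropped} subjects with incomplete "
                      "condition blocks")
    df = df[df["subject_id"].isin(complete)]
    n = df["subject_id"].nunique()
    if n < 2:
        raise InsufficientDataError(
            f"need >= 2 complete subjects, got {n}")
    res = AnovaRM(df, depvar="D_f", subject="subject_id",
                  within=["condition"]).fit()
    row = res.anova_table.iloc[0]
    return AnovaResult(F=float(row["F Value"]),
                       df_num=int(row["Num DF"]), df_den=int(row["Den DF"]),
                       p=float(row["Pr > F"]), n_subjects=n,
                       n_conditions=len(conds),
                       n_dropped_subjects=n_dropped)


def interrater_agreement(table_r1: pd.DataFrame,
                         table_r2: pd.DataFrame) -> tuple[float, float, int]:
    """Pearson r of D_f over sessions matched across two raters.

    Sessions are matched on (subject_id, visit, condition); returns
    ``(r, p, n_matched)``.
    """
    keys = ["subject_id", "visit", "condition"]
    merged = _usable(table_r1).merge(_usable(table_r2), on=keys,
                                     suffixes=("_1", "_2"))
    merged = merged.dropna(subset=["D_f_1", "D_f_2"])
    if len(merged) < 3:
        raise InsufficientDataError(
            f"need >= 3 matched sessions, got {len(merged)}")
    r, p = stats.pearsonr(merged["D_f_1"], merged["D_f_2"])
    return float(r), float(p), len(merged)
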