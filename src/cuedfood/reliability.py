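"""Test-retest reliability: ICC(A,1), applied across the study's measures.

The intraclass correlation used throughout is the two-way random-effects,
absolute-agreement, single-measure coefficient ICC(A,1).  With n measurement
units (subjects or items) in rows and k sessions in columns, the two-way
ANOVA decomposition gives row, column, and error mean squares (MSR, MSC,
MSE) and

    ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)).

The F statistic against ICC = 0 is MSR/MSE; its second degree of freedom and
the 95% confidence bounds use the Satterthwaite approximation, which is why
df2 is generally fractional.  Estimates are interpreted with the
conventional bins Poor (< 0.40), Fair (0.40-0.60), Good (0.60-0.75),
Excellent (0.75-1.0); bins are left-closed so e.g. exactly 0.60 reads Good.

Higher-level helpers compute the study's reliability tables: healthier-choice
frequencies per condition (and their difference), taste/health ratings per
subject or per item, and fitted rstDDM parameters across sessions, plus the
paired comparison of per-subject parameter ranges (max - min over sessions)
between conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .params import PARAM_NAMES

#: left-closed interpretation bins
LABEL_BINS = ((0.40, "Poor"), (0.60, "Fair"), (0.75, "Good"), (np.inf, "Excellent"))


def icc_label(estimate: float) -> str:
    """Qualitative label for an ICC estimate (left-closed bins)."""
    if not np.isfinite(estimate):
        return "undefined"
    for upper, label in LABEL_BINS:
        if estimate < upper:
            return label
    return "Excellent"


@dataclass(frozen=True)
class ICCResult:
    """ICC(A,1) estimate with its F test, Satterthwaite df, CI, and label."""

    estimate: float
    f_value: float
    df1: float
    df2: float
    p_value: float
    ci_low: float
    ci_high: float
    label: str
    n_rows: int
    n_cols: int
    degenerate: bool = False

    def __repr__(self) -> str:  # compact, table-friendly
        return (f"ICC(A,1)={self.estimate:.3f} [{self.ci_low:.3f}, "
                f"{self.ci_high:.3f}] F({self.df1:g},{self.df2:.1f})="
                f"{self.f_value:.2f} ({self.label})")


def as_measure_matrix(matrix, min_rows: int = 2, min_cols: int = 2) -> np.ndarray:
    """Validate and complete-case a units-by-sessions measurement matrix.

    Rows with any missing value are dropped (listwise deletion) with a
    warning carrying the count; the result must keep at least ``min_rows``
    rows and ``min_cols`` columns.
    """
    arr = np.asarray(pd.DataFrame(matrix), dtype=float)
    if arr.ndim != 2:
        raise ValueError("measurement matrix must be 2-D (units x sessions)")
    complete = ~np.isnan(arr).any(axis=1)
    dropped = int((~complete).sum())
    if dropped:
        warnings.warn(f"dropping {dropped} incomplete row(s) listwise", stacklevel=3)
    arr = arr[complete]
    if arr.shape[0] < min_rows or arr.shape[1] < min_cols:
        raise ValueError(
            f"need at least {min_rows}x{min_cols} complete matrix, got {arr.shape}"
        )
    return arr


def icc_a1(matrix, conf_level: float = 0.95) -> ICCResult:
    """ICC(A,1) with F statistic, Satterthwaite df2, and confidence interval.

    A matrix with (numerically) zero total variance yields a degenerate
    result with ``estimate = NaN`` and the ``degenerate`` flag set instead of
    an error or a NaN crash downstream.
    """
    arr = as_measure_matrix(matrix)
    n, k = arr.shape
    grand = arr.mean()
    row_means = arr.mean(axis=1)
    col_means = arr.mean(axis=0)
    sst = float(((arr - grand) ** 2).sum())
    ssr = float(k * ((row_means - grand) ** 2).sum())
    ssc = float(n * ((col_means - grand) ** 2).sum())
    sse = max(sst - ssr - ssc, 0.0)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    if sst <= 1e-12 * max(1.0, abs(grand)) ** 2:
        return ICCResult(np.nan, np.nan, n - 1, np.nan, np.nan, np.nan, np.nan,
                         "undefined", n, k, degenerate=True)

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    est = (msr - mse) / denom if denom > 0 else np.nan

    alpha = 1.0 - conf_level
    if mse > 0 and np.isfinite(est):
        f_value = msr / mse
        r = est
        a = (k * r) / (n * (1.0 - r)) if r < 1 else np.inf
        b = 1.0 + (k * r * (n - 1)) / (n * (1.0 - r)) if r < 1 else np.inf
        if np.isfinite(a) and np.isfinite(b):
            v_num = (a * msc + b * mse) ** 2
            v_den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            df2 = v_num / v_den if v_den > 0 else np.nan
        else:
            df2 = np.nan
        p = float(stats.f.sf(f_value, n - 1, df2)) if np.isfinite(df2) else np.nan
        if np.isfinite(df2):
            fl = stats.f.ppf(1 - alpha / 2, n - 1, df2)
            fu = stats.f.ppf(1 - alpha / 2, df2, n - 1)
            ci_low = (n * (msr - fl * mse)
                      / (fl * (k * msc + (k * n - k - n) * mse) + n * msr))
            ci_high = (n * (fu * msr - mse)
                       / (k * msc + (k * n - k - n) * mse + n * fu * msr))
        else:
            ci_low = ci_high = np.nan
    else:
        # zero error variance: perfect agreement up to row/column effects
        f_value = np.inf
        df2 = float((n - 1) * (k - 1))
        p = 0.0
        ci_low = ci_high = est
    return ICCResult(float(est), float(f_value), float(n - 1), float(df2),
                     float(p), float(ci_low), float(ci_high),
                     icc_label(est), n, k)


# ---------------------------------------------------------------------------
# study-level reliability analyses
# ---------------------------------------------------------------------------

def choice_frequency_reliability(
    trials: pd.DataFrame, conf_level: float = 0.95
) -> dict[str, ICCResult]:
    """ICC(A,1) of per-subject healthier-choice frequencies over sessions.

    Returns results for each cue condition separately and for the
    health-minus-natural difference score.  All five sessions must be
    present; subjects with missing cells are dropped listwise.
    """
    df = trials.loc[~trials["censored"].astype(bool)]
    df = df[df["chose_healthier"] >= 0]
    sessions = sorted(df["session"].unique())
    if len(sessions) < 5:
        raise ValueError(f"choice reliability needs 5 sessions, got {sessions}")
    freq = (
        df.groupby(["subject_id", "session", "condition"])["chose_healthier"]
        .mean()
        .unstack("condition")
    )
    out: dict[str, ICCResult] = {}
    for key in ("natural", "health"):
        mat = freq[key].unstack("session")
        out[key] = icc_a1(mat, conf_level)
    diff = (freq["health"] - freq["natural"]).unstack("session")
    out["difference"] = icc_a1(diff, conf_level)
    return out


def rating_reliability(
    ratings: pd.DataFrame,
    unit: str = "subject",
    sessions: tuple[int, ...] | None = None,
    conf_level: float = 0.95,
) -> pd.DataFrame:
    """Per-unit rating ICCs, summarised as mean +/- sd per attribute.

    ``unit="subject"``: one ICC per subject from an items-by-sessions matrix
    (the item set is restricted to items rated in every requested session).
    ``unit="item"``: one ICC per item from a subjects-by-sessions matrix.
    Returns a tidy frame with one row per attribute carrying the mean, sd,
    and count of per-unit ICC estimates.
    """
    if unit not in ("subject", "item"):
        raise ValueError("unit must be 'subject' or 'item'")
    df = ratings.copy()
    if sessions is not None:
        df = df[df["session"].isin(sessions)]
        missing = set(sessions) - set(df["session"].unique())
        if missing:
            raise ValueError(f"requested sessions absent from ratings: {missing}")
    rows = []
    index_col = "subject_id" if unit == "subject" else "item_id"
    other_col = "item_id" if unit == "subject" else "subject_id"
    for attribute, block in df.groupby("attribute"):
        wide = block.pivot_table(index=[index_col, other_col], columns="session",
                                 values="value")
        wide = wide.dropna(axis=0)        # units x sessions complete cases
        estimates = []
        for unit_id, mat in wide.groupby(level=0):
            if len(mat) < 2:
                continue
            res = icc_a1(mat.to_numpy(), conf_level)
            if not res.degenerate:
                estimates.append({"unit_id": unit_id, "icc": res.estimate,
                                  "label": res.label})
        if not estimates:
            raise ValueError(
                f"no unit had enough overlapping ratings for attribute "
                f"{attribute!r} in sessions {sessions}"
            )
        per_unit = pd.DataFrame(estimates)
        rows.append({
            "attribute": attribute, "unit": unit,
            "icc_mean": float(per_unit["icc"].mean()),
            "icc_sd": float(per_unit["icc"].std(ddof=1)),
            "n_units": int(len(per_unit)),
            "per_unit": per_unit,
        })
    return pd.DataFrame(rows)


def _subject_parameter_table(fit_results: dict) -> pd.DataFrame:
    """Stack subject-level estimates from {(condition, session): FitResult}."""
    frames = []
    for (condition, session), fit in fit_results.items():
        sub = fit.subject_estimates.copy()
        sub["condition"] = condition
        sub["session"] = session
        frames.append(sub)
    return pd.concat(frames, ignore_index=True)


def parameter_reliability(
    fit_results: dict, conf_level: float = 0.95
) -> pd.DataFrame:
    """ICC(A,1) of fitted parameters over sessions, per condition and for the
    health-minus-natural difference scores.

    ``fit_results`` maps (condition, session) to a
    :class:`~cuedfood.inference.FitResult`; the same subjects must be fitted
    in every cell.  Returns a tidy table, one row per parameter x condition.
    """
    table = _subject_parameter_table(fit_results)
    conditions = sorted(table["condition"].unique())
    rows = []
    for parameter in PARAM_NAMES:
        block = table[table["parameter"] == parameter]
        wide = block.pivot_table(index="subject_id", columns=["condition", "session"],
                                 values="estimate")
        for condition in conditions:
            res = icc_a1(wide[condition], conf_level)
            rows.append(_icc_row(parameter, condition, res))
        if set(conditions) >= {"natural", "health"}:
            diff = wide["health"] - wide["natural"]
            res = icc_a1(diff, conf_level)
            rows.append(_icc_row(parameter, "health-natural", res))
    return pd.DataFrame(rows)


def _icc_row(parameter: str, condition: str, res: ICCResult) -> dict:
    return {
        "parameter": parameter, "condition": condition,
        "icc": res.estimate, "f_value": res.f_value, "df1": res.df1,
        "df2": res.df2, "p_value": res.p_value,
        "ci_low": res.ci_low, "ci_high": res.ci_high, "label": res.label,
        "degenerate": res.degenerate,
    }


def parameter_range_comparison(fit_results: dict) -> pd.DataFrame:
    """Stability of subject-level parameters: per-subject max-min range across
    sessions in each condition, compared between conditions by paired t-test.

    Returns one row per parameter with the mean range per condition and the
    paired two-sided t statistic, df, and p value (health minus natural).
    """
    table = _subject_parameter_table(fit_results)
    rows = []
    for parameter in PARAM_NAMES:
        block = table[table["parameter"] == parameter]
        ranges = (
            block.pivot_table(index="subject_id", columns=["condition", "session"],
                              values="estimate")
            .T.groupby(level="condition").agg(lambda s: s.max() - s.min()).T
        )
        ranges = ranges.dropna()
        if len(ranges) < 2:
            raise ValueError("paired range comparison needs at least 2 subjects")
        diff = ranges["health"] - ranges["natural"]
        if np.allclose(diff, 0.0):
            t_stat, p_value = 0.0, 1.0
        else:
            t_stat, p_value = stats.ttest_rel(ranges["health"], ranges["natural"])
        rows.append({
            "parameter": parameter,
            "mean_range_natural": float(ranges["natural"].mean()),
            "mean_range_health": float(ranges["health"].mean()),
            "t_stat": float(t_stat),
            "df": int(len(ranges) - 1),
            "p_value": float(p_value),
        })
    return pd.DataFrame(rows)
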