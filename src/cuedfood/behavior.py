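"""Choice and response-time regressions, and prediction-from-ratings accuracy.

Two hierarchical regressions mirror the study's analyses:

* a logistic model of choosing the healthier option as a function of the
  taste difference (td) and health difference (hd, both coded healthier
  minus less-healthy), cue condition, and session — all interactions except
  td-by-hd;
* a linear model of log RT adding the challenge indicator, with hd/td
  z-scored.

Both are estimated with the summary-statistics (two-stage) hierarchy: the
full fixed-effect structure is fit per subject (statsmodels GLM / OLS), and
population-level coefficients are the across-subject means with
t-distribution 95% intervals.  Every population term therefore has an exact
subject-level counterpart.

The prediction analyses ask how well session-1 information predicts choices:
either through the fitted choice model (classify by predicted probability
vs 0.5) or by the raw rule "pick the item rated tastier (healthier) in
session 1".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

CHOICE_FORMULA = (
    "chose_healthier ~ (hd + td) * C(condition, Treatment('natural'))"
    " * C(session, Treatment(1))"
)
RT_FORMULA = (
    "log_rt ~ (hd_z + td_z) * C(condition, Treatment('natural'))"
    " * C(session, Treatment(1)) * C(challenge)"
)

#: absolute per-subject coefficient beyond which we flag (quasi-)separation
SEPARATION_LIMIT = 15.0


@dataclass
class RegressionResult:
    """Population and per-subject coefficients with 95% intervals."""

    population: pd.DataFrame          # term, estimate, ci_low, ci_high, se
    subject: pd.DataFrame             # subject_id, term, estimate
    formula: str
    flags: dict = field(default_factory=dict)

    def coef(self, term: str) -> float:
        return float(self.population.set_index("term").loc[term, "estimate"])

    def interval(self, term: str) -> tuple[float, float]:
        row = self.population.set_index("term").loc[term]
        return float(row["ci_low"]), float(row["ci_high"])

    def to_tidy(self) -> pd.DataFrame:
        pop = self.population.assign(level="population", subject_id=pd.NA)
        sub = self.subject.assign(level="subject", ci_low=np.nan, ci_high=np.nan,
                                  se=np.nan)
        cols = ["level", "subject_id", "term", "estimate", "se",
                "ci_low", "ci_high"]
        return pd.concat([pop[cols], sub[cols]], ignore_index=True)


def _two_stage(df: pd.DataFrame, formula: str, family) -> RegressionResult:
    sub_rows = []
    flagged = []
    terms = None
    for subject_id, block in df.groupby("subject_id"):
        params = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.glm(formula, data=block, family=family)
            try:
                params = model.fit(maxiter=200).params
            except Exception:  # noqa: BLE001 - fall through to the ridge refit
                params = None
            if (params is None or np.any(~np.isfinite(params))
                    or np.max(np.abs(params)) > SEPARATION_LIMIT):
                # (quasi-)separation: refit with a light ridge penalty so the
                # subject contributes a finite, tamed coefficient vector
                # instead of being dropped
                try:
                    params = model.fit_regularized(alpha=1e-3, L1_wt=0.0).params
                    flagged.append((int(subject_id), "separation: ridge refit"))
                except Exception as exc:  # noqa: BLE001
                    flagged.append((int(subject_id), f"failed: {exc}"))
                    params = None
        if params is None or np.any(~np.isfinite(params)):
            continue
        terms = list(params.index)
        for term, value in params.items():
            sub_rows.append({"subject_id": int(subject_id), "term": term,
                             "estimate": float(value)})
    subject = pd.DataFrame(sub_rows)
    if subject.empty:
        raise ValueError(f"no subject-level fits succeeded: {flagged}")
    n = subject["subject_id"].nunique()
    tcrit = stats.t.ppf(0.975, n - 1) if n > 1 else np.nan
    pop_rows = []
    for term in terms:
        vals = subject.loc[subject["term"] == term, "estimate"].to_numpy()
        mean = float(vals.mean())
        se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan
        pop_rows.append({"term": term, "estimate": mean, "se": se,
                         "ci_low": mean - tcrit * se, "ci_high": mean + tcrit * se})
    flags = {"separation": flagged} if flagged else {}
    return RegressionResult(population=pd.DataFrame(pop_rows), subject=subject,
                            formula=formula, flags=flags)


def _prepare(trials: pd.DataFrame, need_sessions: int = 2) -> pd.DataFrame:
    df = trials.loc[~trials["censored"].astype(bool)].copy()
    if df["condition"].nunique() < 2:
        raise ValueError("both cue conditions must be present")
    if df["session"].nunique() < need_sessions:
        raise ValueError(f"need at least {need_sessions} sessions")
    return df


def fit_choice_model(trials: pd.DataFrame, z_score: bool = False) -> RegressionResult:
    """Hierarchical logistic regression of healthier-choice outcomes.

    hd/td enter in raw rating units by default (``z_score=True`` standardises
    them); condition and session are categorical with natural / session 1 as
    reference levels; censored trials are excluded.
    """
    df = _prepare(trials)
    df = df[df["chose_healthier"] >= 0].copy()
    if z_score:
        for c in ("hd", "td"):
            df[c] = (df[c] - df[c].mean()) / df[c].std(ddof=0)
    return _two_stage(df, CHOICE_FORMULA, sm.families.Binomial())


def fit_rt_model(trials: pd.DataFrame) -> RegressionResult:
    """Hierarchical linear regression of log response times.

    hd/td are z-scored over the analysed trials (as the RT analysis
    specifies); the challenge indicator marks taste-health conflict pairs.
    """
    df = _prepare(trials)
    if (df["rt"] <= 0).any():
        raise ValueError("all response times must be positive")
    df["log_rt"] = np.log(df["rt"].to_numpy(dtype=float))
    for c in ("hd", "td"):
        df[c + "_z"] = (df[c] - df[c].mean()) / df[c].std(ddof=0)
    df["challenge"] = df["challenge"].astype(int)
    return _two_stage(df, RT_FORMULA, sm.families.Gaussian())


# ---------------------------------------------------------------------------
# prediction-from-ratings analyses
# ---------------------------------------------------------------------------

def predict_accuracy_model(
    result: RegressionResult, trials: pd.DataFrame, by_session: bool = False
):
    """Fraction of choices matching the fitted choice model's classification.

    Each non-censored trial is classified as "healthier chosen" when the
    subject-level predicted probability exceeds 0.5 (population coefficients
    are used for subjects without their own fit).  Returns the overall
    proportion correct, or a per-session Series with ``by_session=True``.
    """
    import patsy

    df = trials.loc[~trials["censored"].astype(bool)]
    df = df[df["chose_healthier"] >= 0].copy()
    pop = result.population.set_index("term")["estimate"]
    X = patsy.dmatrix(result.formula.split("~", 1)[1], df, return_type="dataframe")
    X = X[pop.index]
    subj_coefs = result.subject.pivot(index="subject_id", columns="term",
                                      values="estimate")
    beta = np.tile(pop.to_numpy(), (len(df), 1))
    for sid, row in subj_coefs.iterrows():
        mask = (df["subject_id"] == sid).to_numpy()
        beta[mask] = row[pop.index].to_numpy()
    eta = np.sum(X.to_numpy() * beta, axis=1)
    predicted = (1.0 / (1.0 + np.exp(-eta))) > 0.5
    correct = predicted == (df["chose_healthier"].to_numpy() == 1)
    if by_session:
        return pd.Series(correct, index=df.index).groupby(df["session"]).mean()
    return float(np.mean(correct))


def predict_accuracy_attribute(
    ratings_session1: pd.DataFrame, trials: pd.DataFrame, attribute: str
) -> pd.DataFrame:
    """Accuracy of "choose the item rated higher on ``attribute`` in session 1".

    Returns one row per condition with the across-subject mean accuracy, its
    SE, the number of classified trials, and the tally of excluded trials
    (rating ties on the attribute, or censored).
    """
    if attribute not in ("taste", "health"):
        raise ValueError("attribute must be 'taste' or 'health'")
    r1 = ratings_session1[(ratings_session1["session"] == 1)
                          & (ratings_session1["attribute"] == attribute)]
    lookup = r1.set_index(["subject_id", "item_id"])["value"]

    df = trials.loc[~trials["censored"].astype(bool)].copy()
    df = df[df["chose_left"] >= 0]
    left = lookup.reindex(
        pd.MultiIndex.from_frame(df[["subject_id", "left_item"]])
    ).to_numpy()
    right = lookup.reindex(
        pd.MultiIndex.from_frame(df[["subject_id", "right_item"]])
    ).to_numpy()
    if np.isnan(left).any() or np.isnan(right).any():
        raise ValueError("some trial items lack a session-1 rating")
    tie = left == right
    correct = np.where(left > right, df["chose_left"] == 1, df["chose_left"] == 0)

    rows = []
    for condition, block in df.assign(tie=tie, correct=correct).groupby("condition"):
        used = block[~block["tie"]]
        per_subj = used.groupby("subject_id")["correct"].mean()
        rows.append({
            "condition": condition,
            "accuracy": float(per_subj.mean()),
            "se": float(per_subj.std(ddof=1) / np.sqrt(len(per_subj)))
            if len(per_subj) > 1 else np.nan,
            "n_trials": int(len(used)),
            "n_excluded_ties": int(block["tie"].sum()),
        })
    return pd.DataFrame(rows)
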