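"""Tidy table readers/writers with schema validation.

All study artefacts are plain delimited text: ``ratings.tsv`` (subject,
session, item, attribute, value), ``trials.tsv`` (one row per choice trial),
and ``truth.json`` (generative parameters of a synthetic run).  Readers
validate the documented schema and report offending rows by number.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .params import PARAM_NAMES
from .synthetic import SimulatedStudy

RATINGS_COLUMNS = ["subject_id", "session", "item_id", "attribute", "value"]
TRIALS_COLUMNS = [
    "subject_id", "session", "condition", "block_index", "trial",
    "left_item", "right_item", "healthier_side", "challenge",
    "hd", "td", "hd_lr", "td_lr", "chose_left", "chose_healthier",
    "rt", "censored",
]

RT_DEADLINE = 3.0


class SchemaError(ValueError):
    pass


def _check_columns(df: pd.DataFrame, expected: list[str], name: str) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing columns {missing}; "
                          f"found {list(df.columns)}")


def _report_rows(mask: np.ndarray, what: str, name: str) -> None:
    bad = np.nonzero(mask)[0]
    if bad.size:
        head = ", ".join(str(i) for i in bad[:10])
        raise SchemaError(
            f"{name}: {bad.size} row(s) with {what}; first offenders "
            f"(0-based): {head}"
        )


def write_ratings(ratings: pd.DataFrame, path) -> None:
    ratings[RATINGS_COLUMNS].to_csv(path, sep="\t", index=False)


def read_ratings(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _check_columns(df, RATINGS_COLUMNS, "ratings")
    _report_rows(~df["attribute"].isin(["taste", "health"]).to_numpy(),
                 "attribute not in {taste, health}", "ratings")
    v = df["value"].to_numpy(dtype=float)
    _report_rows(~np.isfinite(v) | (v < -5) | (v > 5),
                 "value outside [-5, 5]", "ratings")
    return df


def write_trials(trials: pd.DataFrame, path) -> None:
    trials[TRIALS_COLUMNS].to_csv(path, sep="\t", index=False,
                                  float_format="%.6f")


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _check_columns(df, TRIALS_COLUMNS, "trials")
    _report_rows(~df["condition"].isin(["natural", "health"]).to_numpy(),
                 "condition not in {natural, health}", "trials")
    censored = df["censored"].astype(bool).to_numpy()
    rt = df["rt"].to_numpy(dtype=float)
    _report_rows(~censored & ~np.isfinite(rt), "non-finite rt on responded "
                 "trials", "trials")
    out_of_range = ~censored & ((rt <= 0) | (rt > RT_DEADLINE))
    if out_of_range.any():
        rows = ", ".join(str(i) for i in np.nonzero(out_of_range)[0][:10])
        warnings.warn(
            f"trials: {int(out_of_range.sum())} responded trial(s) with rt "
            f"outside (0, {RT_DEADLINE}]; first rows: {rows}", stacklevel=2,
        )
    return df


def write_truth(study: SimulatedStudy, path) -> None:
    payload = {
        f"{s}|{c}|{k}": {n: getattr(p, n) for n in PARAM_NAMES}
        for (s, c, k), p in sorted(study.truth.items())
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path) -> pd.DataFrame:
    payload = json.loads(Path(path).read_text())
    rows = []
    for key, vals in payload.items():
        subject_id, condition, session = key.split("|")
        rows.append({"subject_id": int(subject_id), "condition": condition,
                     "session": int(session), **vals})
    return pd.DataFrame(rows)


def load_study_tables(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load ``trials.tsv`` and ``ratings.tsv`` from a study directory."""
    path = Path(path)
    trials = read_trials(path / "trials.tsv")
    ratings = read_ratings(path / "ratings.tsv")
    return trials, ratings
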