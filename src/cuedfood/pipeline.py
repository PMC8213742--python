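"""End-to-end synthetic study runs: simulate -> fit -> regress -> reliability.

A run is described by a :class:`RunConfig` (YAML- or JSON-loadable, validated
by pydantic so a missing or malformed field is reported by name), executed
stage by stage into an output directory of plain-text artefacts::

    ratings.tsv   trials.tsv   truth.json    config.yaml
    fits.tsv      fit_diagnostics.json
    regressions.tsv
    reliability.tsv
    report.md     run.log

Every stage re-reads its inputs from the run directory, so stages can be
re-run individually from the CLI.  The whole synthetic path is deterministic
in the configured seed; the log records the config hash and stage timings.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import behavior, inference, io, reliability, synthetic

logger = logging.getLogger("cuedfood")

STAGES = ("simulate", "fit", "regress", "reliability", "report")


class StageError(RuntimeError):
    """A pipeline stage failed; earlier outputs remain on disk."""


class RunConfig(BaseModel):
    """Configuration of one synthetic study run."""

    seed: int
    outdir: str
    n_subjects: int = Field(default=10, ge=5)
    n_items: int = Field(default=synthetic.N_ITEMS, ge=2)
    sessions: list[int] = Field(default=[1, 2, 3, 4, 5])
    challenge_fraction: float = Field(default=0.5, ge=0.0, le=1.0)
    between_sd: float = Field(default=1.0, ge=0.0)
    within_sd_taste: float = Field(default=2.6, ge=0.0)
    within_sd_health: float = Field(default=1.5, ge=0.0)
    stable_subjects: bool = True
    dt: float = Field(default=0.002, gt=0.0)
    fit_mode: str = "two_stage"
    fit_sessions: list[int] = Field(default=[1, 2, 3, 4, 5])
    fit_conditions: list[str] = Field(default=["natural", "health"])
    min_trials: int = Field(default=30, ge=5)
    conservation_tol: float = Field(default=1e-4, gt=0.0)
    make_figure: bool = True

    @field_validator("fit_mode")
    @classmethod
    def _check_mode(cls, v: str) -> str:
        if v not in ("two_stage", "mcmc"):
            raise ValueError("fit_mode must be 'two_stage' or 'mcmc'")
        return v

    @field_validator("sessions", "fit_sessions")
    @classmethod
    def _check_sessions(cls, v: list[int]) -> list[int]:
        if not v or any(s < 1 or s > 5 for s in v):
            raise ValueError("sessions must be a non-empty subset of 1..5")
        return sorted(set(v))

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls(**data)


def _stage(name):
    def wrap(fn):
        def inner(self, *a, **kw):
            t0 = time.time()
            logger.info("stage %s: start", name)
            try:
                out = fn(self, *a, **kw)
            except Exception as exc:
                logger.error("stage %s: FAILED: %s", name, exc)
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done in %.1f s", name, time.time() - t0)
            return out
        inner.__name__ = fn.__name__
        return inner
    return wrap


class StudyRunner:
    """Executes the pipeline stages for one configured run."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(self.outdir / "run.log")
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
        logger.info("run configured: seed=%d hash=%s", config.seed,
                    config.config_hash())

    # -- stage 1 ------------------------------------------------------------
    @_stage("simulate")
    def simulate(self) -> synthetic.SimulatedStudy:
        cfg = self.config
        study = synthetic.simulate_study(
            n_subjects=cfg.n_subjects, n_items=cfg.n_items,
            sessions=tuple(cfg.sessions),
            stable_subjects=cfg.stable_subjects,
            challenge_fraction=cfg.challenge_fraction,
            between_sd=cfg.between_sd,
            within_sd={"taste": cfg.within_sd_taste,
                       "health": cfg.within_sd_health},
            dt=cfg.dt, seed=cfg.seed,
        )
        io.write_ratings(study.ratings, self.outdir / "ratings.tsv")
        io.write_trials(study.trials, self.outdir / "trials.tsv")
        io.write_truth(study, self.outdir / "truth.json")
        (self.outdir / "config.yaml").write_text(
            yaml.safe_dump(self.config.model_dump())
        )
        cens = study.trials["censored"].mean()
        logger.info("simulated %d trials, censoring rate %.3f",
                    len(study.trials), cens)
        return study

    # -- stage 2 ------------------------------------------------------------
    @_stage("fit")
    def fit(self) -> pd.DataFrame:
        cfg = self.config
        trials, _ = io.load_study_tables(self.outdir)
        ocfg = inference.desk_optimizer_config()
        ocfg.min_trials = cfg.min_trials
        tidy = []
        diagnostics = {}
        rng = np.random.default_rng(cfg.seed + 1)
        for session in cfg.fit_sessions:
            for condition in cfg.fit_conditions:
                cell = trials[(trials["session"] == session)
                              & (trials["condition"] == condition)]
                by_subject = {
                    int(s): g for s, g in cell.groupby("subject_id")
                }
                fit = inference.fit_hierarchical(
                    by_subject, mode=cfg.fit_mode, optimizer_config=ocfg,
                    seed=int(rng.integers(2**31 - 1)),
                    condition=condition, session=session,
                )
                tidy.append(fit.to_tidy())
                diagnostics[f"{condition}|{session}"] = _jsonable(fit.diagnostics)
        fits = pd.concat(tidy, ignore_index=True)
        fits.to_csv(self.outdir / "fits.tsv", sep="\t", index=False,
                    float_format="%.6f")
        (self.outdir / "fit_diagnostics.json").write_text(
            json.dumps(diagnostics, indent=1)
        )
        return fits

    # -- stage 3 ------------------------------------------------------------
    @_stage("regress")
    def regress(self) -> pd.DataFrame:
        trials, _ = io.load_study_tables(self.outdir)
        choice = behavior.fit_choice_model(trials)
        rt = behavior.fit_rt_model(trials)
        out = pd.concat(
            [choice.to_tidy().assign(model="choice"),
             rt.to_tidy().assign(model="rt")], ignore_index=True,
        )
        out.to_csv(self.outdir / "regressions.tsv", sep="\t", index=False,
                   float_format="%.6f")
        return out

    # -- stage 4 ------------------------------------------------------------
    @_stage("reliability")
    def reliability(self) -> pd.DataFrame:
        cfg = self.config
        trials, ratings = io.load_study_tables(self.outdir)
        rows = []
        if trials["session"].nunique() >= 5:
            freq = reliability.choice_frequency_reliability(trials)
            for key, res in freq.items():
                rows.append(reliability._icc_row("choice_frequency", key, res))
        else:
            logger.info("reliability: <5 sessions, skipping choice frequencies")
        for unit in ("subject", "item"):
            try:
                summary = reliability.rating_reliability(
                    ratings, unit=unit, sessions=tuple(cfg.sessions)
                )
            except ValueError as exc:
                logger.info("reliability: skipping rating/%s (%s)", unit, exc)
                continue
            for _, r in summary.iterrows():
                rows.append({
                    "parameter": f"rating_{r['attribute']}",
                    "condition": f"per-{unit}",
                    "icc": r["icc_mean"], "f_value": np.nan, "df1": np.nan,
                    "df2": np.nan, "p_value": np.nan,
                    "ci_low": r["icc_mean"] - r["icc_sd"],
                    "ci_high": r["icc_mean"] + r["icc_sd"],
                    "label": reliability.icc_label(r["icc_mean"]),
                    "degenerate": False,
                })
        fits_path = self.outdir / "fits.tsv"
        if fits_path.exists() and len(cfg.fit_sessions) >= 2:
            fits = pd.read_csv(fits_path, sep="\t")
            fit_results = _fits_to_results(fits)
            rows.extend(
                reliability.parameter_reliability(fit_results)
                .to_dict("records")
            )
            ranges = reliability.parameter_range_comparison(fit_results)
            ranges.to_csv(self.outdir / "parameter_ranges.tsv", sep="\t",
                          index=False, float_format="%.6f")
        else:
            logger.info("reliability: <2 fitted sessions, skipping parameters")
        table = pd.DataFrame(rows)
        table.to_csv(self.outdir / "reliability.tsv", sep="\t", index=False,
                     float_format="%.6f")
        return table

    # -- stage 5 ------------------------------------------------------------
    @_stage("report")
    def report(self) -> Path:
        trials, _ = io.load_study_tables(self.outdir)
        resp = trials[(~trials["censored"].astype(bool))
                      & (trials["chose_healthier"] >= 0)]
        freq = (resp.groupby(["session", "condition"])["chose_healthier"]
                .mean().unstack("condition"))
        lines = [
            "# Synthetic cued-attribute study report",
            "",
            f"- config hash: `{self.config.config_hash()}`",
            f"- seed: {self.config.seed}",
            f"- subjects: {self.config.n_subjects}, "
            f"sessions: {self.config.sessions}",
            f"- trials: {len(trials)} "
            f"(censored: {trials['censored'].mean():.3f})",
            "",
            "## Healthier-choice proportion by session",
            "",
            freq.round(3).to_markdown(),
        ]
        for name in ("reliability.tsv", "regressions.tsv", "fits.tsv"):
            if (self.outdir / name).exists():
                lines.append(f"\nSee `{name}`.")
        if self.config.make_figure:
            try:
                import matplotlib
                matplotlib.use("Agg")
                import matplotlib.pyplot as plt

                fig, ax = plt.subplots(figsize=(5, 3.2))
                for cond, marker in (("natural", "o"), ("health", "s")):
                    if cond in freq.columns:
                        ax.plot(freq.index, freq[cond], marker=marker, label=cond)
                ax.set_xlabel("session")
                ax.set_ylabel("P(healthier choice)")
                ax.set_ylim(0, 1)
                ax.legend(title="cue")
                fig.tight_layout()
                fig.savefig(self.outdir / "report_choices.png", dpi=120)
                plt.close(fig)
                lines.append("\n![healthier choices](report_choices.png)")
            except Exception as exc:  # noqa: BLE001 - figure is best-effort
                logger.warning("report figure failed: %s", exc)
        path = self.outdir / "report.md"
        path.write_text("\n".join(lines) + "\n")
        return path

    def run_all(self) -> Path:
        self.simulate()
        self.fit()
        self.regress()
        self.reliability()
        self.report()
        return self.outdir


def run_synthetic_study(config: RunConfig) -> Path:
    """Execute all stages of a configured synthetic study run."""
    return StudyRunner(config).run_all()


def load_study_tables(path):
    """Re-export of :func:`cuedfood.io.load_study_tables`."""
    return io.load_study_tables(path)


def _fits_to_results(fits: pd.DataFrame) -> dict:
    """Regroup a tidy fits table into {(condition, session): FitResult}."""
    out = {}
    subj = fits[fits["level"] == "subject"]
    for (condition, session), block in subj.groupby(["condition", "session"]):
        sub = block[["subject_id", "parameter", "estimate", "se"]].copy()
        grp = (fits[(fits["level"] == "group")
                    & (fits["condition"] == condition)
                    & (fits["session"] == session)]
               [["parameter", "estimate", "se"]]
               .rename(columns={"estimate": "mean"}))
        grp["sd"] = np.nan
        grp["ci_low"] = np.nan
        grp["ci_high"] = np.nan
        out[(condition, int(session))] = inference.FitResult(
            subject_estimates=sub, group=grp, diagnostics={},
            condition=condition, session=int(session),
        )
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
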