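"""Study-shaped synthetic data: items, ratings, session designs, choices.

Emulates the cued-attribute food choice study design: 23 participants, five
sessions over two weeks; taste and health ratings of 180 food items on a
continuous -5..+5 scale (all 180 items in sessions 1 and 5, a fixed 60-item
subset in sessions 2-4); ~210 choice trials per session split into 9
health-cued and 8 natural-cued blocks; pairs built from each subject's
session-1 ratings so that choosing the healthier item often means forgoing
the tastier one ("challenge" pairs); a 3-second response deadline.

Every generator takes an explicit seed and is byte-reproducible.  Simulated
choices come from :mod:`cuedfood.rstddm` with known ground-truth parameters,
so every downstream stage (fitting, regressions, reliability) can be tested
against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import rstddm
from .params import PARAM_NAMES, RstDDMParams

# ---------------------------------------------------------------------------
# design constants of the task
# ---------------------------------------------------------------------------
N_SUBJECTS = 23
N_ITEMS = 180
N_SUBSET_ITEMS = 60
N_SESSIONS = 5
N_TRIALS = 210
N_HEALTH_BLOCKS = 9
N_NATURAL_BLOCKS = 8
HEALTH_TRIALS_MEAN = 110.6   # per-session health-cued trial count, mean
TRIALS_JITTER_SD = 5.2       # and its across-session/subject sd
DEADLINE = 3.0
RATING_SCALE = (-5.0, 5.0)
CONDITIONS = ("natural", "health")
FULL_RATING_SESSIONS = (1, 5)

# ---------------------------------------------------------------------------
# published group-level rstDDM estimates (mean, spread) per session/condition,
# used as the generative defaults for synthetic cohorts.  The spread column is
# on the scale of the between-subject standard deviation (see docs/methods.md)
# and is used as the default sd when drawing subject-level parameters.
# ---------------------------------------------------------------------------
STUDY_GROUP_PARAMS: dict[str, dict[int, dict[str, tuple[float, float]]]] = {
    "natural": {
        1: {"drift_bias": (0.02, 0.08), "w_health": (-0.13, 0.31),
            "w_taste": (0.89, 0.48), "rst": (0.18, 0.08), "ndt": (0.60, 0.16),
            "sp_bias": (0.49, 0.03), "noise": (1.02, 0.13)},
        2: {"drift_bias": (-0.03, 0.10), "w_health": (0.05, 0.48),
            "w_taste": (0.69, 0.28), "rst": (0.14, 0.13), "ndt": (0.59, 0.09),
            "sp_bias": (0.50, 0.04), "noise": (1.02, 0.14)},
        3: {"drift_bias": (0.02, 0.11), "w_health": (0.03, 0.47),
            "w_taste": (0.73, 0.31), "rst": (0.02, 0.02), "ndt": (0.58, 0.15),
            "sp_bias": (0.50, 0.03), "noise": (1.08, 0.13)},
        4: {"drift_bias": (0.08, 0.17), "w_health": (-0.01, 0.62),
            "w_taste": (0.72, 0.39), "rst": (0.04, 0.03), "ndt": (0.54, 0.11),
            "sp_bias": (0.48, 0.04), "noise": (1.08, 0.16)},
        5: {"drift_bias": (-0.03, 0.13), "w_health": (0.00, 0.49),
            "w_taste": (0.87, 0.49), "rst": (0.10, 0.06), "ndt": (0.55, 0.09),
            "sp_bias": (0.50, 0.04), "noise": (1.09, 0.12)},
    },
    "health": {
        1: {"drift_bias": (0.05, 0.07), "w_health": (0.90, 0.46),
            "w_taste": (0.32, 0.32), "rst": (-0.03, 0.02), "ndt": (0.59, 0.13),
            "sp_bias": (0.49, 0.03), "noise": (0.98, 0.13)},
        2: {"drift_bias": (0.07, 0.13), "w_health": (0.82, 0.55),
            "w_taste": (0.29, 0.23), "rst": (-0.04, 0.02), "ndt": (0.57, 0.10),
            "sp_bias": (0.48, 0.04), "noise": (1.01, 0.12)},
        3: {"drift_bias": (0.01, 0.12), "w_health": (0.80, 0.50),
            "w_taste": (0.30, 0.29), "rst": (-0.03, 0.03), "ndt": (0.53, 0.15),
            "sp_bias": (0.49, 0.04), "noise": (1.00, 0.09)},
        4: {"drift_bias": (0.08, 0.07), "w_health": (0.68, 0.65),
            "w_taste": (0.33, 0.31), "rst": (-0.02, 0.02), "ndt": (0.54, 0.10),
            "sp_bias": (0.48, 0.04), "noise": (1.08, 0.12)},
        5: {"drift_bias": (-0.05, 0.09), "w_health": (0.80, 0.63),
            "w_taste": (0.32, 0.44), "rst": (-0.05, 0.04), "ndt": (0.52, 0.10),
            "sp_bias": (0.51, 0.04), "noise": (1.03, 0.13)},
    },
}

#: hard physiological/identifiability clips applied to drawn subject params
_PARAM_CLIPS = {
    "noise": (0.4, 3.0),
    "sp_bias": (0.2, 0.8),
    "ndt": (0.15, 1.5),
    "rst": (-1.0, 1.0),
    "w_taste": (-3.0, 3.0),
    "w_health": (-3.0, 3.0),
    "drift_bias": (-2.0, 2.0),
}


class DesignError(ValueError):
    """Raised when a requested design cannot be constructed."""


# ---------------------------------------------------------------------------
# items and ratings
# ---------------------------------------------------------------------------

def gen_items(n_items: int, seed: int, taste_health_corr: float = -0.3) -> pd.DataFrame:
    """Latent taste/health values for a synthetic food-image set.

    A Gaussian copula with uniform marginals on the rating scale gives
    latents that span the full -5..+5 range with a tunable taste-health
    correlation (negative by default: tastier snacks tend to be less
    healthy, which is what makes challenge pairs plentiful).
    """
    if n_items < 2:
        raise DesignError(f"need at least 2 items, got {n_items}")
    if not -1.0 < taste_health_corr < 1.0:
        raise ValueError("taste_health_corr must lie in (-1, 1)")
    rng = np.random.default_rng(seed)
    cov = np.array([[1.0, taste_health_corr], [taste_health_corr, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n_items,
                                method="cholesky")
    from scipy.stats import norm

    lo, hi = RATING_SCALE
    u = norm.cdf(z)
    latents = lo + (hi - lo) * u
    return pd.DataFrame(
        {
            "item_id": np.arange(n_items, dtype=int),
            "latent_taste": latents[:, 0],
            "latent_health": latents[:, 1],
        }
    )


def subset_items(items: pd.DataFrame, n_subset: int = N_SUBSET_ITEMS) -> np.ndarray:
    """Fixed middle-session subset chosen to span the taste range."""
    if len(items) <= n_subset:
        return items["item_id"].to_numpy()
    order = items.sort_values("latent_taste")["item_id"].to_numpy()
    idx = np.linspace(0, len(order) - 1, n_subset).round().astype(int)
    return np.sort(order[idx])


def _sd_for(attr: str, sd) -> float:
    if isinstance(sd, dict):
        return float(sd[attr])
    return float(sd)


def gen_ratings(
    items: pd.DataFrame,
    n_subjects: int = N_SUBJECTS,
    sessions: tuple[int, ...] = tuple(range(1, N_SESSIONS + 1)),
    between_sd=1.0,
    within_sd=None,
    seed: int = 0,
) -> pd.DataFrame:
    """Tidy rating records (subject, session, item, attribute, value).

    Each subject's mean rating of an item is the item latent plus a stable
    subject-by-item offset with sd ``between_sd``; each session adds fresh
    noise with sd ``within_sd``.  Both sds may be a scalar or a mapping per
    attribute (default within-session sds emulate the study's observed
    reliabilities: health ratings more repeatable than taste).  Values are
    clipped to the rating scale.  Ignoring the mild clipping, the implied
    test-retest ICC of a rating is

        (var_latent + between_sd^2) / (var_latent + between_sd^2 + within_sd^2)

    with var_latent = 100/12 for the uniform latent marginals.
    """
    if within_sd is None:
        within_sd = {"taste": 2.6, "health": 1.5}
    for attr in ("taste", "health"):
        if _sd_for(attr, between_sd) < 0 or _sd_for(attr, within_sd) < 0:
            raise ValueError("rating sds must be non-negative")
    rng = np.random.default_rng(seed)
    lo, hi = RATING_SCALE
    sub60 = set(subset_items(items))
    records = []
    item_ids = items["item_id"].to_numpy()
    latents = {"taste": items["latent_taste"].to_numpy(),
               "health": items["latent_health"].to_numpy()}
    for subject in range(n_subjects):
        for attr in ("taste", "health"):
            b = _sd_for(attr, between_sd)
            w = _sd_for(attr, within_sd)
            offset = rng.normal(0.0, b, size=len(item_ids)) if b > 0 else 0.0
            subj_mean = latents[attr] + offset
            for session in sessions:
                mask = (
                    np.ones(len(item_ids), dtype=bool)
                    if session in FULL_RATING_SESSIONS
                    else np.isin(item_ids, list(sub60))
                )
                noise = rng.normal(0.0, w, size=mask.sum()) if w > 0 else 0.0
                values = np.clip(subj_mean[mask] + noise, lo, hi)
                records.append(
                    pd.DataFrame(
                        {
                            "subject_id": subject,
                            "session": session,
                            "item_id": item_ids[mask],
                            "attribute": attr,
                            "value": values,
                        }
                    )
                )
    return pd.concat(records, ignore_index=True)


# ---------------------------------------------------------------------------
# session design
# ---------------------------------------------------------------------------

@dataclass
class SessionDesign:
    """One subject's fixed trial list and block structure.

    ``trials`` has one row per trial with the pair, its condition and block,
    the challenge flag, and both attribute-difference codings (healthier
    minus less-healthy for regressions; left minus right for the DDM).
    The same design is reused for all five sessions because pairs are fixed
    by the session-1 ratings.
    """

    subject_id: int
    blocks: list = field(default_factory=list)  # [(condition, n_trials), ...]
    trials: pd.DataFrame = field(default_factory=pd.DataFrame)


def build_design(
    ratings_session1: pd.DataFrame,
    n_trials: int = N_TRIALS,
    challenge_fraction: float = 0.5,
    seed: int = 0,
    challenge_td_window: float | None = None,
    subject_id: int | None = None,
) -> SessionDesign:
    """Build one subject's 210-trial, 17-block choice design.

    ``ratings_session1`` must hold that subject's session-1 taste and health
    ratings.  The healthier item of a pair is the one with the higher
    session-1 health rating (exact health ties are excluded).  A challenge
    pair is one whose tastier-rated item is strictly less healthy; when
    ``challenge_td_window`` is set, the two taste ratings must additionally
    lie within that window of each other.
    """
    rng = np.random.default_rng(seed)
    wide = ratings_session1.pivot_table(
        index="item_id", columns="attribute", values="value"
    )
    if not {"taste", "health"}.issubset(wide.columns) or wide.isna().any().any():
        raise DesignError("session-1 taste and health ratings required for all items")
    if subject_id is None:
        subject_id = int(ratings_session1["subject_id"].iloc[0])

    ids = wide.index.to_numpy()
    taste = wide["taste"].to_numpy()
    health = wide["health"].to_numpy()
    ii, jj = np.triu_indices(len(ids), k=1)
    dh = health[ii] - health[jj]
    keep = dh != 0                      # exact health ties excluded
    ii, jj, dh = ii[keep], jj[keep], dh[keep]
    # orient so that index h is the healthier item
    h_idx = np.where(dh > 0, ii, jj)
    l_idx = np.where(dh > 0, jj, ii)
    hd = health[h_idx] - health[l_idx]              # > 0 by construction
    td = taste[h_idx] - taste[l_idx]                # healthier minus less-healthy
    challenge = td < 0                              # tastier item is less healthy
    if challenge_td_window is not None:
        challenge &= np.abs(td) <= challenge_td_window

    n_chal = int(round(challenge_fraction * n_trials))
    n_other = n_trials - n_chal
    pool_c = np.nonzero(challenge)[0]
    pool_o = np.nonzero(~challenge)[0]
    if len(pool_c) < n_chal or len(pool_o) < n_other:
        raise DesignError(
            f"not enough pairs: need {n_chal} challenge ({len(pool_c)} available) "
            f"and {n_other} non-challenge ({len(pool_o)} available)"
        )
    chosen = np.concatenate(
        [rng.choice(pool_c, n_chal, replace=False),
         rng.choice(pool_o, n_other, replace=False)]
    )
    rng.shuffle(chosen)

    # block structure: 9 health-cued + 8 natural-cued blocks in random order,
    # condition totals jittered around the study's reported means
    health_total = int(round(rng.normal(HEALTH_TRIALS_MEAN, TRIALS_JITTER_SD)))
    health_total = int(np.clip(health_total, N_HEALTH_BLOCKS,
                               n_trials - N_NATURAL_BLOCKS))
    natural_total = n_trials - health_total

    def split(total: int, k: int) -> np.ndarray:
        base = np.full(k, total // k)
        extra = rng.choice(k, total % k, replace=False)
        base[extra] += 1
        return base

    labels = ["health"] * N_HEALTH_BLOCKS + ["natural"] * N_NATURAL_BLOCKS
    sizes = np.concatenate(
        [split(health_total, N_HEALTH_BLOCKS), split(natural_total, N_NATURAL_BLOCKS)]
    )
    order = rng.permutation(len(labels))
    blocks = [(labels[k], int(sizes[k])) for k in order]

    healthier_left = rng.random(n_trials) < 0.5
    h_items = ids[h_idx[chosen]]
    l_items = ids[l_idx[chosen]]
    rows = {
        "subject_id": subject_id,
        "trial": np.arange(n_trials),
        "block_index": np.repeat(np.arange(len(blocks)), [b[1] for b in blocks]),
        "condition": np.repeat([b[0] for b in blocks], [b[1] for b in blocks]),
        "left_item": np.where(healthier_left, h_items, l_items),
        "right_item": np.where(healthier_left, l_items, h_items),
        "healthier_side": np.where(healthier_left, "left", "right"),
        "challenge": challenge[chosen],
        "hd": hd[chosen],
        "td": td[chosen],
        "hd_lr": np.where(healthier_left, hd[chosen], -hd[chosen]),
        "td_lr": np.where(healthier_left, td[chosen], -td[chosen]),
    }
    return SessionDesign(subject_id=subject_id, blocks=blocks,
                         trials=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# subject-level parameters and choice simulation
# ---------------------------------------------------------------------------

def draw_cohort(
    group_means: dict[str, float],
    group_sds: dict[str, float],
    n_subjects: int,
    seed: int,
    center: bool = True,
) -> list[RstDDMParams]:
    """Draw subject parameter sets around group means.

    With ``center=True`` (default) the drawn offsets are re-centred so the
    realized cohort mean equals the target group mean exactly; recovery
    error then measures the estimator rather than cohort sampling noise.
    Draws are clipped to broad validity ranges (noise > 0, sp in (0, 1), ...).
    """
    rng = np.random.default_rng(seed)
    draws = {}
    for name in PARAM_NAMES:
        z = rng.standard_normal(n_subjects)
        if center and n_subjects > 1:
            z = z - z.mean()
        vals = group_means[name] + group_sds.get(name, 0.0) * z
        lo, hi = _PARAM_CLIPS[name]
        draws[name] = np.clip(vals, lo, hi)
    return [
        RstDDMParams(**{name: float(draws[name][s]) for name in PARAM_NAMES})
        for s in range(n_subjects)
    ]


def group_param_spec(condition: str, session: int = 1):
    """(means, sds) dictionaries for one published condition/session cell."""
    cell = STUDY_GROUP_PARAMS[condition][session]
    means = {k: v[0] for k, v in cell.items()}
    sds = {k: v[1] for k, v in cell.items()}
    return means, sds


def simulate_dataset(
    designs: dict[int, SessionDesign],
    params: dict[tuple[int, str, int], RstDDMParams],
    sessions: tuple[int, ...] = tuple(range(1, N_SESSIONS + 1)),
    dt: float = 0.002,
    seed: int = 0,
    deadline: float = DEADLINE,
) -> pd.DataFrame:
    """Simulate choice trials for every subject, session, and condition.

    ``params`` maps (subject_id, condition, session) to that cell's
    generative parameter set.  Returns a tidy trial table; censored trials
    (no response before the deadline) are retained with ``censored=True``,
    ``rt = NaN`` and choice codes of -1.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    seq = np.random.SeedSequence(seed)
    out = []
    for subject_id in sorted(designs):
        design = designs[subject_id]
        for session in sessions:
            for condition in CONDITIONS:
                sub = design.trials[design.trials["condition"] == condition]
                if sub.empty:
                    continue
                p = params[(subject_id, condition, session)]
                child_seed = int(seq.spawn(1)[0].generate_state(1)[0] % (2**31 - 1))
                sim = rstddm.simulate_trials(
                    p, sub["td_lr"].to_numpy(), sub["hd_lr"].to_numpy(),
                    dt=dt, deadline=deadline, seed=child_seed,
                )
                block = sub.copy().reset_index(drop=True)
                block["session"] = session
                block["chose_left"] = sim["chose_left"].to_numpy()
                block["rt"] = sim["rt"].to_numpy()
                block["censored"] = sim["censored"].to_numpy()
                left_is_healthier = (block["healthier_side"] == "left").to_numpy()
                cl = block["chose_left"].to_numpy()
                ch = np.where(cl < 0, -1,
                              ((cl == 1) == left_is_healthier).astype(int))
                block["chose_healthier"] = ch.astype(np.int8)
                out.append(block)
    trials = pd.concat(out, ignore_index=True)
    cols = ["subject_id", "session", "condition", "block_index", "trial",
            "left_item", "right_item", "healthier_side", "challenge",
            "hd", "td", "hd_lr", "td_lr", "chose_left", "chose_healthier",
            "rt", "censored"]
    return trials[cols]


@dataclass
class SimulatedStudy:
    """Bundle of everything one synthetic study run produces."""

    items: pd.DataFrame
    ratings: pd.DataFrame
    designs: dict[int, SessionDesign]
    truth: dict[tuple[int, str, int], RstDDMParams]
    trials: pd.DataFrame

    def truth_frame(self) -> pd.DataFrame:
        rows = [
            {"subject_id": s, "condition": c, "session": k,
             **{n: getattr(p, n) for n in PARAM_NAMES}}
            for (s, c, k), p in sorted(self.truth.items())
        ]
        return pd.DataFrame(rows)


def simulate_study(
    n_subjects: int = N_SUBJECTS,
    n_items: int = N_ITEMS,
    sessions: tuple[int, ...] = tuple(range(1, N_SESSIONS + 1)),
    group_params: dict | None = None,
    stable_subjects: bool = True,
    challenge_fraction: float = 0.5,
    between_sd=1.0,
    within_sd=None,
    dt: float = 0.002,
    seed: int = 0,
    center_cohort: bool = True,
) -> SimulatedStudy:
    """End-to-end synthetic study: items -> ratings -> designs -> choices.

    ``group_params`` defaults to the published per-session group estimates.
    With ``stable_subjects=True`` each subject's deviation from the group
    mean is drawn once and carried across sessions (the generative basis of
    test-retest reliability); otherwise subjects are redrawn independently
    every session and between-session reliability collapses by construction.
    """
    if group_params is None:
        group_params = STUDY_GROUP_PARAMS
    seq = np.random.SeedSequence(seed)
    s_items, s_ratings, s_design, s_params, s_sim = (
        int(s.generate_state(1)[0] % (2**31 - 1)) for s in seq.spawn(5)
    )
    items = gen_items(n_items, seed=s_items)
    ratings = gen_ratings(items, n_subjects, sessions=sessions,
                          between_sd=between_sd, within_sd=within_sd,
                          seed=s_ratings)
    designs = {}
    for subject in range(n_subjects):
        r1 = ratings[(ratings["subject_id"] == subject) & (ratings["session"] == 1)]
        designs[subject] = build_design(
            r1, challenge_fraction=challenge_fraction,
            seed=s_design + subject, subject_id=subject,
        )

    truth: dict[tuple[int, str, int], RstDDMParams] = {}
    prng = np.random.default_rng(s_params)
    for condition in CONDITIONS:
        # one standard-normal offset per subject/parameter, reused across
        # sessions when subjects are stable
        stable_z = {
            name: _centered_normal(prng, n_subjects, center_cohort)
            for name in PARAM_NAMES
        }
        for session in sessions:
            means, sds = group_param_spec_from(group_params, condition, session)
            z = stable_z if stable_subjects else {
                name: _centered_normal(prng, n_subjects, center_cohort)
                for name in PARAM_NAMES
            }
            for subject in range(n_subjects):
                vals = {}
                for name in PARAM_NAMES:
                    v = means[name] + sds.get(name, 0.0) * z[name][subject]
                    lo, hi = _PARAM_CLIPS[name]
                    vals[name] = float(np.clip(v, lo, hi))
                truth[(subject, condition, session)] = RstDDMParams(**vals)

    trials = simulate_dataset(designs, truth, sessions=sessions, dt=dt, seed=s_sim)
    return SimulatedStudy(items=items, ratings=ratings, designs=designs,
                          truth=truth, trials=trials)


def _centered_normal(rng: np.random.Generator, n: int, center: bool) -> np.ndarray:
    z = rng.standard_normal(n)
    if center and n > 1:
        z = z - z.mean()
    return z


def group_param_spec_from(table: dict, condition: str, session: int):
    cell = table[condition][session]
    means = {k: v[0] for k, v in cell.items()}
    sds = {k: v[1] for k, v in cell.items()}
    return means, sds
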