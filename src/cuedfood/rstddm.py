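"""Core relative-starting-time DDM: simulation, FPT density, likelihood.

The accumulator starts at ``x0 = 2*sp_bias - 1`` between fixed thresholds
-1 (right option) and +1 (left option) and evolves as

    dx = mu(t) dt + noise dW,

where the drift is ``drift_bias`` plus each attribute's weighted left-minus-
right rating difference once that attribute's onset has passed.  Onsets are
measured within decision time (after the non-decision time): the earlier
attribute starts at 0 and the later one at ``|rst|``, with the sign of
``rst`` selecting which attribute lags (positive ``rst`` = health lags).
The drift is therefore piecewise constant with a single switch, which both
the Euler–Maruyama simulator and the Fokker–Planck solver exploit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._kernels import _fpt_march, _loglik_kernel, _simulate_kernel
from .params import RstDDMParams

#: default solver resolution for likelihood evaluation (speed-oriented)
LIK_NX = 101
LIK_DT = 0.01
#: finer default for the user-facing density (accuracy-oriented)
DENSITY_NX = 201
DENSITY_DT = 0.0025
#: per-trial density floor, keeps the log-likelihood finite for outlier RTs
LIK_FLOOR = 1e-10

DEADLINE = 3.0  # response window in seconds

TRIAL_COLUMNS = ("td_lr", "hd_lr", "chose_left", "rt", "censored")


def effective_drifts(params: RstDDMParams, td_lr, hd_lr):
    """Piecewise-constant drift decomposition (mu_before, mu_after, t_switch).

    ``t_switch`` is ``|rst|``; before it only the earlier attribute (plus the
    drift bias) contributes, after it both do.
    """
    td_lr = np.asarray(td_lr, dtype=float)
    hd_lr = np.asarray(hd_lr, dtype=float)
    full = params.drift_bias + params.w_taste * td_lr + params.w_health * hd_lr
    if params.rst > 0:          # taste first, health delayed
        pre = params.drift_bias + params.w_taste * td_lr
    elif params.rst < 0:        # health first, taste delayed
        pre = params.drift_bias + params.w_health * hd_lr
    else:
        pre = full
    return np.broadcast_arrays(pre, full)[0].copy(), full, abs(params.rst)


def drift_at(params: RstDDMParams, td_lr: float, hd_lr: float, t_decision):
    """Drift rate at decision time ``t_decision`` (seconds after onset)."""
    t = np.asarray(t_decision, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_decision must be >= 0")
    on_t, on_h = params.onset_taste, params.onset_health
    mu = (
        params.drift_bias
        + params.w_taste * td_lr * (t >= on_t)
        + params.w_health * hd_lr * (t >= on_h)
    )
    return mu if mu.ndim else float(mu)


def _as_param_arrays(params: RstDDMParams, td_lr, hd_lr, deadline):
    td_lr = np.atleast_1d(np.asarray(td_lr, dtype=float))
    hd_lr = np.atleast_1d(np.asarray(hd_lr, dtype=float))
    if not (np.all(np.isfinite(td_lr)) and np.all(np.isfinite(hd_lr))):
        raise ValueError("attribute differences must be finite")
    if deadline <= params.ndt:
        raise ValueError("deadline must exceed the non-decision time")
    mu1, mu2, tsw = effective_drifts(params, td_lr, hd_lr)
    n = mu1.shape[0]
    return (
        mu1,
        mu2,
        np.full(n, tsw),
        np.full(n, params.x0),
        np.full(n, params.noise),
        np.full(n, deadline - params.ndt),
    )


def simulate_trials(
    params: RstDDMParams,
    td_lr,
    hd_lr,
    dt: float = 0.002,
    deadline: float = DEADLINE,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate one trial per (td_lr, hd_lr) pair with shared parameters.

    Returns a tidy frame with columns ``td_lr, hd_lr, chose_left, rt,
    censored``; censored trials (no threshold crossing before the deadline,
    non-decision time included) carry ``rt = NaN`` and ``chose_left = -1``.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    mu1, mu2, tsw, x0, noise, t_max = _as_param_arrays(params, td_lr, hd_lr, deadline)
    choice, dec_t = _simulate_kernel(mu1, mu2, tsw, x0, noise, t_max, dt,
                                     int(seed) % (2**31 - 1))
    rt = dec_t + params.ndt
    censored = choice < 0
    rt[censored] = np.nan
    return pd.DataFrame(
        {
            "td_lr": np.atleast_1d(np.asarray(td_lr, dtype=float)),
            "hd_lr": np.atleast_1d(np.asarray(hd_lr, dtype=float)),
            "chose_left": choice.astype(np.int8),
            "rt": rt,
            "censored": censored,
        }
    )


def simulate_trial(
    params: RstDDMParams,
    td_lr: float,
    hd_lr: float,
    dt: float = 0.002,
    deadline: float = DEADLINE,
    seed: int = 0,
):
    """Single-trial convenience wrapper: returns (chose_left, rt, censored)."""
    df = simulate_trials(params, [td_lr], [hd_lr], dt=dt, deadline=deadline, seed=seed)
    row = df.iloc[0]
    censored = bool(row.censored)
    return (None if censored else bool(row.chose_left == 1),
            None if censored else float(row.rt),
            censored)


@dataclass(frozen=True)
class FPTDensity:
    """First-passage densities on a time grid (decision time, seconds).

    ``upper``/``lower`` are sub-probability densities of absorbing at +1 / -1;
    ``survival`` is the probability mass still between the thresholds at each
    grid time, so absorbed + surviving mass is conserved at 1.
    """

    t: np.ndarray
    upper: np.ndarray
    lower: np.ndarray
    survival: np.ndarray

    def absorbed_mass(self) -> float:
        """Mass absorbed by the end of the grid (trapezoidal in time)."""
        return float(np.trapezoid(self.upper + self.lower, self.t))


def _check_stability(params: RstDDMParams, mu1, mu2, nx: int) -> None:
    h = 2.0 / (nx - 1)
    pe = max(np.max(np.abs(mu1)), np.max(np.abs(mu2))) * h / params.noise**2
    if pe > 2.0:
        raise ValueError(
            f"grid too coarse: cell Peclet number |mu|*h/noise^2 = {pe:.2f} "
            f"exceeds 2 (nx={nx}); increase nx or reduce the drift magnitude"
        )


def fpt_density(
    params: RstDDMParams,
    td_lr: float,
    hd_lr: float,
    t_grid,
    nx: int = DENSITY_NX,
    dt_max: float = DENSITY_DT,
) -> FPTDensity:
    """First-passage-time density by finite differences on the Fokker–Planck
    equation with absorbing thresholds and the piecewise-constant rstDDM drift.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size == 0:
        raise ValueError("t_grid must be a non-empty 1-D array")
    if np.any(np.diff(t_grid) <= 0) or t_grid[0] <= 0:
        raise ValueError("t_grid must be strictly increasing and positive")
    mu1, mu2, tsw = effective_drifts(params, [td_lr], [hd_lr])
    _check_stability(params, mu1, mu2, nx)
    g_up, g_lo, surv = _fpt_march(
        float(mu1[0]), float(mu2[0]), float(tsw), params.x0, params.noise,
        t_grid, nx, dt_max,
    )
    return FPTDensity(t=t_grid, upper=g_up, lower=g_lo, survival=surv)


def loglik(
    params: RstDDMParams,
    trials: pd.DataFrame,
    nx: int = LIK_NX,
    dt_max: float = LIK_DT,
    floor: float = LIK_FLOOR,
    deadline: float = DEADLINE,
    deadline_policy: str = "exclude",
) -> float:
    """Trial-wise log-likelihood of choices and RTs under the rstDDM.

    Censored trials are excluded (``deadline_policy="exclude"``, default) or
    the per-trial density is renormalised by the probability of responding
    before the deadline (``"truncate"``).  The density of each kept trial is
    evaluated at the chosen threshold and decision time ``rt - ndt`` and
    floored at ``floor`` before taking logs.
    """
    if deadline_policy not in ("exclude", "truncate"):
        raise ValueError(f"unknown deadline_policy {deadline_policy!r}")
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trials table is missing columns {missing}")
    kept = trials.loc[~trials["censored"].astype(bool)]
    if kept.empty:
        warnings.warn("no non-censored trials; log-likelihood is 0", stacklevel=2)
        return 0.0
    tau = kept["rt"].to_numpy(dtype=float) - params.ndt
    bad = np.nonzero(tau <= 0)[0]
    if bad.size:
        idx = kept.index[bad[0]]
        raise ValueError(
            f"trial {idx}: rt={kept['rt'].iloc[bad[0]]:.4f} s does not exceed "
            f"ndt={params.ndt:.4f} s"
        )
    mu1, mu2, tsw, x0, noise, _ = _as_param_arrays(
        params, kept["td_lr"].to_numpy(), kept["hd_lr"].to_numpy(), deadline
    )
    _check_stability(params, mu1, mu2, nx)
    if deadline_policy == "truncate":
        t_norm = np.full(tau.shape[0], deadline - params.ndt)
    else:
        t_norm = np.zeros(tau.shape[0])
    chose_left = kept["chose_left"].to_numpy(dtype=np.int8)
    return float(
        _loglik_kernel(mu1, mu2, tsw, float(x0[0]), float(noise[0]), tau,
                       chose_left, nx, dt_max, floor, t_norm)
    )
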