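"""Closed forms for the constant-drift special case (``rst = 0``).

With a single constant drift the rstDDM reduces to the standard two-threshold
diffusion model, for which the absorption probability and the first-passage
time density have classical closed forms.  These serve as independent oracles
for the stochastic simulator and for the finite-difference solver, and as
initialisation heuristics for the fitters.

Conventions match :mod:`cuedfood.params`: thresholds at -1 (lower/right) and
+1 (upper/left); ``x0`` is the accumulator's starting position in (-1, 1);
times are decision times (non-decision time already removed).
"""

from __future__ import annotations

import numpy as np

_L = 2.0  # threshold separation


def prob_upper(mu: float, x0: float = 0.0, noise: float = 1.0) -> float:
    """Probability that a constant-drift diffusion is absorbed at +1 first.

    Uses the scale-function solution of the two-boundary absorption problem;
    reduces to the linear interpolation ``(x0 + 1) / 2`` as ``mu -> 0``.
    """
    w = x0 + 1.0
    theta = 2.0 * mu / noise**2
    if abs(theta) < 1e-9:
        # second-order expansion, numerically stable through mu = 0
        return w / _L + theta * w * (_L - w) / (2.0 * _L)
    return float(np.expm1(-theta * w) / np.expm1(-theta * _L))


def _fpt_lower_series(
    t: np.ndarray, mu: float, w: float, noise: float, max_terms: int = 4000
) -> np.ndarray:
    """Large-time series for the density of absorption at the lower threshold.

    ``w`` is the start position measured from the lower threshold (in (0, 2)).
    The series is summed until the largest remaining term magnitude falls
    below 1e-14 of the running total at every requested time.
    """
    t = np.asarray(t, dtype=float)
    s2 = noise**2
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    acc = np.zeros_like(tp)
    lam = np.pi**2 * s2 / (2.0 * _L**2)
    for k in range(1, max_terms + 1):
        term = k * np.sin(k * np.pi * w / _L) * np.exp(-lam * k**2 * tp)
        acc += term
        # decay envelope: once exp factor is negligible everywhere, stop
        if np.all(k * np.exp(-lam * k**2 * tp) < 1e-14):
            break
    pref = (np.pi * s2 / _L**2) * np.exp(-mu * w / s2 - mu**2 * tp / (2.0 * s2))
    out[pos] = np.maximum(pref * acc, 0.0)
    return out


def fpt_density_constant_drift(
    t, mu: float, x0: float = 0.0, noise: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """First-passage-time densities (upper, lower) for constant drift.

    Returns the sub-probability densities of absorbing at +1 and at -1 at
    decision time ``t``; each integrates to the corresponding absorption
    probability.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    w = x0 + 1.0
    lower = _fpt_lower_series(t, mu, w, noise)
    upper = _fpt_lower_series(t, -mu, _L - w, noise)
    return upper, lower


def mean_decision_time(mu: float, x0: float = 0.0, noise: float = 1.0) -> float:
    """Expected time to absorption at either threshold (constant drift).

    For non-zero drift this follows from optional stopping:
    ``E[X_T] - x0 = mu * E[T]`` with ``X_T`` at +1 or -1 with the closed-form
    absorption probabilities; the driftless limit is the classical
    ``w * (L - w) / noise**2`` with ``w`` measured from the lower threshold.
    """
    w = x0 + 1.0
    if abs(mu) < 1e-7:
        return float(w * (_L - w) / noise**2)
    p_up = prob_upper(mu, x0, noise)
    return float((_L * p_up - w) / mu)
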