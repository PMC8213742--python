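"""Numba kernels: Euler–Maruyama simulation and Fokker–Planck first passage.

The forward (Fokker–Planck) equation for the accumulator density p(x, t),

    dp/dt = -mu(t) dp/dx + (noise^2 / 2) d2p/dx2,   p(-1, t) = p(+1, t) = 0,

is integrated with a theta-scheme on a uniform grid (Crank–Nicolson after a
few backward-Euler start-up steps that damp the delta initial condition —
the Rannacher trick).  The drift is piecewise constant in time with a single
switch at the later attribute's onset, so the march lands exactly on the
switch time and on every requested evaluation time, and the tridiagonal
elimination factors can be precomputed once per constant-drift segment.
First-passage densities are read off as the outward probability flux at each
threshold using a second-order one-sided derivative.

The simulator applies a Brownian-bridge crossing test within each Euler step,
which removes the O(sqrt(dt)) bias from discrete threshold checks.
"""

import numpy as np
from numba import njit

#: backward-Euler start-up steps before switching to Crank–Nicolson
N_RANNACHER = 3


@njit(cache=True)
def _march_segment(p, mu, s2, h, dt, theta, nsteps, cp, inv_beta, out):
    """Advance the interior density ``nsteps`` steps of size ``dt``.

    Implicit side solved by the Thomas algorithm with elimination factors
    precomputed once for the whole segment (constant drift and step size).
    """
    m = p.shape[0]
    # implicit matrix rows [a, b, c]
    diff = s2 / (2.0 * h * h)
    adv = mu / (2.0 * h)
    a = -theta * dt * (diff + adv)
    b = 1.0 + theta * dt * 2.0 * diff
    c = -theta * dt * (diff - adv)
    ib = 1.0 / b
    inv_beta[0] = ib
    cp[0] = c * ib
    for j in range(1, m):
        ib = 1.0 / (b - a * cp[j - 1])
        inv_beta[j] = ib
        cp[j] = c * ib
    # explicit side coefficients
    w = (1.0 - theta) * dt
    la = w * (diff + adv)
    ld = 1.0 - w * 2.0 * diff
    lu = w * (diff - adv)
    for _ in range(nsteps):
        prev = 0.0
        for j in range(m):
            r = ld * p[j]
            if j > 0:
                r += la * p[j - 1]
            if j < m - 1:
                r += lu * p[j + 1]
            prev = (r - a * prev) * inv_beta[j]
            out[j] = prev
        for j in range(m - 2, -1, -1):
            out[j] -= cp[j] * out[j + 1]
        for j in range(m):
            p[j] = out[j] if out[j] > 0.0 else 0.0


@njit(cache=True)
def _boundary_flux(p, s2, h):
    """Outward flux (g_upper, g_lower) from the interior density."""
    m = p.shape[0]
    if m >= 3:
        # third-order one-sided derivative with p = 0 on the threshold
        g_up = s2 * (18.0 * p[m - 1] - 9.0 * p[m - 2] + 2.0 * p[m - 3]) / (12.0 * h)
        g_lo = s2 * (18.0 * p[0] - 9.0 * p[1] + 2.0 * p[2]) / (12.0 * h)
    elif m == 2:
        g_up = s2 * (4.0 * p[m - 1] - p[m - 2]) / (4.0 * h)
        g_lo = s2 * (4.0 * p[0] - p[1]) / (4.0 * h)
    else:
        g_up = s2 * p[m - 1] / (2.0 * h)
        g_lo = s2 * p[0] / (2.0 * h)
    if g_up < 0.0:
        g_up = 0.0
    if g_lo < 0.0:
        g_lo = 0.0
    return g_up, g_lo


@njit(cache=True)
def _fpt_march(mu1, mu2, tsw, x0, noise, t_eval, nx, dt_max):
    """March the density to each time in sorted ``t_eval``.

    Returns (g_up, g_lo, survival) sampled at t_eval.  ``tsw`` is the drift
    switch time; ``mu1`` applies before it and ``mu2`` after.
    """
    n_eval = t_eval.shape[0]
    g_up = np.zeros(n_eval)
    g_lo = np.zeros(n_eval)
    surv = np.zeros(n_eval)
    m = nx - 2                      # interior nodes
    h = 2.0 / (nx - 1)
    s2 = noise * noise

    p = np.zeros(m)
    cp = np.empty(m)
    inv_beta = np.empty(m)
    out = np.empty(m)

    # delta initial condition split linearly over the two flanking grid nodes
    pos = (x0 + 1.0) / h            # fractional node index in the full grid
    j = int(pos)                    # mass goes to full-grid nodes j and j+1
    frac = pos - j
    if j < 1:
        j, frac = 1, 0.0            # x0 hugging the lower threshold
    if j >= nx - 2:
        j, frac = nx - 2, 0.0       # hugging the upper threshold
    p[j - 1] += (1.0 - frac) / h
    if frac > 0.0 and j <= nx - 3:
        p[j] += frac / h

    t = 0.0
    step_count = 0
    for i in range(n_eval):
        target = t_eval[i]
        while t < target - 1e-12:
            if tsw > 0.0 and t < tsw - 1e-12:
                mu = mu1
                seg_end = tsw if tsw < target else target
            else:
                mu = mu2
                seg_end = target
            span = seg_end - t
            nsub = int(np.ceil(span / dt_max - 1e-9))
            if nsub < 1:
                nsub = 1
            dt = span / nsub
            n_be = 0
            if step_count < N_RANNACHER:
                n_be = min(N_RANNACHER - step_count, nsub)
                _march_segment(p, mu, s2, h, dt, 1.0, n_be, cp, inv_beta, out)
                step_count += n_be
            if nsub - n_be > 0:
                _march_segment(p, mu, s2, h, dt, 0.5, nsub - n_be,
                               cp, inv_beta, out)
                step_count += nsub - n_be
            t = seg_end
        gu, gl = _boundary_flux(p, s2, h)
        g_up[i] = gu
        g_lo[i] = gl
        total = 0.0
        for jj in range(m):
            total += p[jj]
        surv[i] = total * h
    return g_up, g_lo, surv


@njit(cache=True)
def _loglik_kernel(mu1, mu2, tsw, x0, noise, tau, chose_left,
                   nx, dt_max, floor, t_norm):
    """Summed log first-passage density over trials.

    ``t_norm[i] > tau[i]`` requests truncation normalisation: the trial
    density is divided by the probability of absorption before ``t_norm[i]``.
    """
    n = tau.shape[0]
    total = 0.0
    for i in range(n):
        if t_norm[i] > tau[i]:
            te = np.empty(2)
            te[0] = tau[i]
            te[1] = t_norm[i]
        else:
            te = np.empty(1)
            te[0] = tau[i]
        g_up, g_lo, surv = _fpt_march(mu1[i], mu2[i], tsw[i], x0, noise,
                                      te, nx, dt_max)
        d = g_up[0] if chose_left[i] == 1 else g_lo[0]
        if t_norm[i] > tau[i]:
            z = 1.0 - surv[te.shape[0] - 1]
            if z > 1e-12:
                d = d / z
        if d < floor:
            d = floor
        total += np.log(d)
    return total


@njit(cache=True)
def _simulate_kernel(mu1, mu2, tsw, x0, noise, t_max, dt, seed):
    """Euler–Maruyama simulation with Brownian-bridge crossing detection.

    Returns (choice, decision_time): choice 1 = upper threshold (left),
    0 = lower (right), -1 = no crossing before t_max (censored).  Between
    step endpoints the conditional (bridge) probability of having touched a
    threshold, exp(-2 (b - x_old)(b - x_new) / (noise^2 dt)), is used so the
    discrete check does not systematically miss within-step excursions.
    """
    np.random.seed(seed)
    n = mu1.shape[0]
    choice = np.empty(n, dtype=np.int8)
    dtime = np.empty(n)
    for i in range(n):
        x = x0[i]
        t = 0.0
        s2dt = noise[i] * noise[i] * dt
        sig = np.sqrt(s2dt)
        ch = np.int8(-1)
        limit = t_max[i]
        while t < limit:
            mu = mu1[i] if t < tsw[i] else mu2[i]
            x_new = x + mu * dt + sig * np.random.randn()
            t += dt
            if x_new >= 1.0:
                ch = np.int8(1)
                break
            if x_new <= -1.0:
                ch = np.int8(0)
                break
            # bridge tests (negligible beyond ~5 s2dt of a threshold)
            du = (1.0 - x) * (1.0 - x_new)
            if du < 5.0 * s2dt and np.random.random() < np.exp(-2.0 * du / s2dt):
                ch = np.int8(1)
                break
            dl = (1.0 + x) * (1.0 + x_new)
            if dl < 5.0 * s2dt and np.random.random() < np.exp(-2.0 * dl / s2dt):
                ch = np.int8(0)
                break
            x = x_new
        choice[i] = ch
        dtime[i] = t if ch >= 0 else np.nan
    return choice, dtime
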