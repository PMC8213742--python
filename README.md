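# cuedfood

Simulation, diffusion modelling, and test-retest reliability analysis for
the **cued-attribute food choice task** — a dietary decision paradigm in
which participants choose between pairs of food images over five sessions,
sometimes after an explicit cue to consider healthiness ("health-cued"
blocks) and sometimes choosing naturally. The package is aimed at decision
neuroscientists and methodologists who want to (a) fit the
relative-starting-time diffusion decision model (rstDDM) to choice/RT data
from this task, (b) quantify how repeatable the task's measures are across
sessions, and (c) stress-test both on synthetic data with known ground
truth.

## The model

A choice is evidence accumulation between absorbing thresholds fixed at
−1 (right item) and +1 (left item):

```
dx = mu(t) dt + sigma dW,        x(0) = 2 sp_bias − 1
mu(t) = drift_bias + w_taste · td · 1[t ≥ onset_taste]
                   + w_health · hd · 1[t ≥ onset_health]
```

where `td`/`hd` are left-minus-right taste and health rating differences
(session-1 ratings, −5..+5 scale). Each attribute starts influencing the
drift at its own latency; the **relative start time**
`RST = onset_health − onset_taste` is positive when taste is considered
first. Response time is the first passage time plus a non-decision time
`NDT`, censored at the 3-s response deadline. With `RST = 0` this is the
standard two-threshold DDM.

The likelihood solves the Fokker–Planck equation with a Crank–Nicolson
scheme (the piecewise-constant drift makes this fast and exact in
structure); subjects are estimated by penalised maximum likelihood on a
transformed scale, and group level either by moment summary ("two-stage")
or by a Metropolis-within-Gibbs normal hierarchy ("mcmc").

Test-retest reliability uses **ICC(A,1)** — two-way random effects,
absolute agreement, single measure — with F statistics, Satterthwaite
degrees of freedom, 95% CIs, and the conventional Poor/Fair/Good/Excellent
bins.

## Worked example

```python
import numpy as np
from cuedfood import RstDDMParams, simulate_trials, fpt_density, icc_a1

p = RstDDMParams(noise=1.0, sp_bias=0.5, ndt=0.5, rst=0.18,
                 w_taste=0.89, w_health=-0.13, drift_bias=0.02)

# simulate 10,000 trials of one choice pair (left item tastier)
trials = simulate_trials(p, np.full(10000, 1.5), np.full(10000, -0.5), seed=1)
print(round((trials.chose_left == 1).mean(), 3),
      round(trials.rt.mean(), 3), round(trials.censored.mean(), 4))
# 0.936 1.118 0.005

# the matching first-passage densities on a grid
d = fpt_density(p, 1.5, -0.5, np.arange(0.01, 2.5, 0.01))
print(round(float(np.trapezoid(d.upper, d.t)), 3))
# 0.937

# reliability of a subjects-by-sessions measurement matrix
rng = np.random.default_rng(0)
mat = rng.normal(0, 2, (23, 1)) + rng.normal(0, 1, (23, 5))
print(icc_a1(mat))
# ICC(A,1)=0.777 [0.645, 0.883] F(22,88.5)=19.30 (Excellent)
```

The first block says: with these natural-cued parameters a pair whose left
item is rated 1.5 points tastier (and 0.5 less healthy) is chosen left 94%
of the time with a mean RT just over 1.1 s, and almost never times out; the
solver integrates to the same choice probability. The ICC example shows a
4:1 signal-to-noise matrix landing in the Excellent band.

An end-to-end synthetic study (ratings → designs → simulated choices →
fits → regressions → reliability report) runs from the CLI:

```bash
cuedfood all --seed 7 --outdir runs/demo            # or --config run.yaml
cuedfood simulate --seed 7 --outdir runs/sim-only   # single stage
```

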