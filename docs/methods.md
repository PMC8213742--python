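# Methods

`cuedfood` implements the analysis path of a five-session cued-attribute
food choice experiment: simulation of the task, fitting of the
relative-starting-time diffusion decision model (rstDDM), the behavioural
regressions, and ICC(A,1) test-retest reliability. This note documents the
models, the numerical choices behind them, and what the synthetic data do
and do not emulate.

## The rstDDM

A binary food choice is modelled as a diffusion between absorbing
thresholds fixed at −1 (right item) and +1 (left item),

    dx = mu(t) dt + sigma dW,     x(0) = 2·z − 1,

with seven free parameters per subject, condition, and session:

| parameter | symbol | units | meaning |
|---|---|---|---|
| `noise` | sigma | a.u./√s | diffusion standard deviation |
| `sp_bias` | z | (0,1) | starting point; 0.5 = midway between thresholds |
| `ndt` | — | s | non-decision time added to the first passage time |
| `rst` | — | s | onset(health) − onset(taste); positive = taste first |
| `w_taste`, `w_health` | — | a.u. per rating unit | drift weights |
| `drift_bias` | — | a.u./s | constant drift intercept |

The drift at decision time *t* is
`drift_bias + w_taste·td_lr·1[t ≥ onset_taste] + w_health·hd_lr·1[t ≥ onset_health]`,
where `td_lr`/`hd_lr` are the left-minus-right session-1 rating differences
in raw rating units. Onsets are anchored **within decision time** — the
earlier attribute starts at 0 and the later at `|rst|` — because the
encoding/motor component is already captured by `ndt`. With `rst = 0` the
model is the standard two-threshold DDM, and all constant-drift closed
forms apply (`cuedfood.analytic`).

### Simulation

Euler–Maruyama with default `dt = 0.002 s`, plus a Brownian-bridge
crossing test inside each step (`exp(−2(b−x)(b−x')/(sigma²dt))`). The
bridge test removes the O(√dt) threshold-miss bias of the naive scheme; at
the default step the simulator matches the analytic absorption probability
to well within Monte-Carlo error at 2×10⁵ trials. Trials whose first
passage plus `ndt` exceeds the 3-s response window are kept but flagged
censored.

### Likelihood

The first-passage-time density solves the Fokker–Planck equation with
absorbing thresholds. Because the drift is piecewise constant with one
switch at `|rst|`, the solver marches a theta-scheme (backward Euler for
the first three steps to damp the delta initial condition, then
Crank–Nicolson) that lands exactly on the switch time and on every
evaluation time; densities are the outward boundary fluxes from a
third-order one-sided derivative. Defaults: 201 space nodes, `dt ≤
0.0025 s` for the user-facing density (mass conservation error < 1e−4 over
a 3-s horizon; sup-norm against the constant-drift series solution
≈ 3×10⁻³); 101 nodes and `dt ≤ 0.01 s` for likelihood evaluation inside
the optimizer. A cell-Péclet check (`|mu|·h/sigma² ≤ 2`) guards the central
advection stencil and raises a named error rather than oscillating.

Censored trials are excluded from the likelihood by default; a
`truncate` policy (renormalising by the probability of responding before
the deadline) is available. Per-trial densities are floored at 1e−10.

## Fitting

Each session × condition cell is fit separately. Subject-level estimation
maximises the penalised log-likelihood on a transformed scale — log noise,
logit starting point, logit NDT scaled to sit just below the subject's
fastest RT, raw RST/weights/bias — with Powell's method and optional
jittered restarts. The penalty is a set of weakly-informative normal
priors (subject MAP). Prior scales come from the task geometry, not from
any fitted result: ratings span ±5 and thresholds sit at ±1, so a drift
weight of ±3 or an attribute-onset lag of ±0.5 s already implies dynamics
far outside the observable 3-s window. The RST prior (sd 0.5 s) matters
most: when one drift weight is near zero the likelihood is flat in RST and
an unpenalised optimum can wander arbitrarily far along the ridge,
dragging the noise and weight estimates with it. This is the same
identifiability failure the task's natural-cued condition produces in real
data, and the package warns whenever a weight's 95% interval covers zero
and RST is reported.

Uncertainty is the inverse observed information (finite-difference Hessian
on the transformed scale, pushed through the transform jacobian).

Two hierarchical modes:

* **two_stage** (default): subject MAP fits, then group moments (mean,
  sd, t-based 95% CI). This is the desk-scale workhorse.
* **mcmc**: Metropolis-within-Gibbs over a normal hierarchy on the
  transformed scale — random-walk subject updates with burn-in scale
  adaptation, conjugate normal/inverse-gamma updates of group means and
  variances, two chains, split-R̂ convergence diagnostics (threshold 1.01,
  flagged not silently dropped). On synthetic checks the two modes agree
  on group means to within 0.1 a.u.

The desk-scale optimizer configuration (single start, 91 nodes,
`dt ≤ 0.012`, ≤600 function evaluations) was fixed by a refinement study:
relative to the default configuration it moves 20-subject group means by
less than 0.02 a.u., an order of magnitude below cohort sampling noise.

## Synthetic data

The generator reproduces the study design exactly: 23 subjects by default,
5 sessions, 180 food items rated on a continuous −5..+5 scale (sessions 1
and 5; a fixed 60-item subset spanning the taste range in sessions 2–4),
and per session 210 choice pairs in 9 health-cued plus 8 natural-cued
blocks whose condition totals are jittered around 110.6 ± 5.2 / 99.3 ± 5.2.
Pairs are built from each subject's session-1 ratings; the healthier item
is the one with the strictly higher session-1 health rating (exact ties
are excluded), and a configurable fraction of pairs are "challenge" pairs
whose tastier item is strictly less healthy (an optional |td| window
implements the "similar ratings" reading of that definition, off by
default since no threshold is published). Session-1 ratings drive the
model and the analyses in all five sessions.

Item latents use a Gaussian copula with uniform marginals on the rating
scale and a taste–health correlation of −0.3 (tastier snacks tend to be
rated less healthy, which makes challenge pairs plentiful). Ratings are
latent + a stable subject×item offset (sd 1.0) + fresh session noise,
clipped to the scale; the implied test-retest ICC is
`(100/12 + between²)/(100/12 + between² + within²)`, and the default
within-session sds (taste 2.6, health 1.5) were chosen so subject-level
rating reliability lands in the fair band for taste and the excellent band
for health, the study's signature pattern.

Generative rstDDM values default to the published per-session,
per-condition group estimates. The spread column of that table is treated
as the **between-subject sd** when drawing cohorts: the published
group-mean HDIs are several times narrower than the printed ± values, so
the ± column cannot be the standard error of the group mean, and ±-as-sd
is the only reading that produces cohorts with realistic heterogeneity.
Cohort draws can be exactly centred (`center=True`, default in the
recovery paths) so the realized cohort mean equals the target value and
recovery error measures the estimator rather than cohort sampling noise.
Subjects' deviations are drawn once and carried across sessions
(`stable_subjects=True`), which is what gives the synthetic study its
test-retest reliability; redrawing per session collapses reliability by
construction and is used as the negative control.

What the generator does **not** emulate: item-level rating reliability is
lower than in real data (the only stable cross-subject structure per item
is the subject×item offset; real raters share session-specific item
effects), session-order effects (practice speed-up, session-2 drift in
natural-cued choices) are absent because each session draws from its own
published parameter cell independently, and there are no lapses,
fast-guess contaminants, or fatigue. Passing tests on synthetic data
therefore validate the estimators and the pipeline, not the psychology.

## Regressions

The choice model is a hierarchical logistic regression of choosing the
healthier item on `(hd + td) * condition * session` (healthier-minus-
less-healthy coding, raw rating units, natural/session-1 reference, no
hd×td term — the sum `(hd + td)` never generates one); the RT model is
the same structure on log RT with the challenge factor added and hd/td
z-scored. Both use the summary-statistics hierarchy: the full fixed-effect
design per subject (GLM/OLS), population level = across-subject mean with
t 95% intervals, so subject-level terms mirror population terms exactly.
Separation or non-convergence flags the subject rather than failing the
analysis. A z-scoring flag exists for the choice model; raw units are the
default because only the RT analysis specifies standardisation.

Prediction analyses classify each trial by the subject-level fitted
probability against 0.5 (`predict_accuracy_model`) or by the higher
session-1 rating on one attribute (`predict_accuracy_attribute`; rating
ties are excluded and tallied).

## Reliability

`icc_a1` computes ICC(A,1) from the two-way ANOVA mean squares, with the
F statistic against zero, Satterthwaite (fractional) df2, and the
F-distribution confidence bounds. It is validated against an independent
brute-force ANOVA implementation to 1e−12 and against pingouin's ICC2.
Interpretation bins are left-closed: Poor < 0.40 ≤ Fair < 0.60 ≤ Good
< 0.75 ≤ Excellent. Zero-variance matrices return a flagged degenerate
result. Missing cells are handled by listwise deletion with a warning.

Per-subject rating ICCs treat items as rows and sessions as columns (the
transposed, per-item analysis is the separate `unit="item"` mode — the
orientation is explicit, not inferred). Parameter reliability runs per
parameter × condition and on health-minus-natural difference scores;
parameter stability uses per-subject max−min ranges across sessions
compared between conditions with a paired two-sided t-test.

## Problem sizes

Desk-scale runs use 20-subject cohorts with ~100 trials per subject for
recovery (the study's per-condition trial count), 10⁵-trial simulations
for the closed-form checks, and 10⁶-trial simulations for
solver-vs-simulator agreement (sup-norm tolerance 0.1, covering histogram
noise plus residual simulator discretisation). The default end-to-end
pipeline configuration fits 10 subjects × 5 sessions × 2 conditions in
two-stage mode.
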