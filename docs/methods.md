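# Methods

`pctsim` simulates behavior and behavior change as negative-feedback
control of perception.  This note documents the models, their parameters,
the numerical choices, and what the bundled synthetic studies do and do
not demonstrate.

## The control unit

The building block is a discrete-time control loop.  A physical input
quantity `Qi` is transformed by an input gain `Ki` into a perception
`p`; the comparator forms the error `e = r − p` against the reference
`r`; the output function amplifies the error by `Ko` inside a leaky
integrator with slowing constant `S` (in iterations); the output
quantity `Qo` acts back on `Qi` through the environmental feedback gain
`Kf` against a disturbance `D`:

    p   ← Ki · Qi(t − d)
    e   ← r − p
    Qo  ← Qo + (Ko · e − Qo) / S
    Qi  ← Kf · Qo(t − d) + D(t)

`d` is a whole-iteration transport delay applied to both the perceptual
and the output path (delay buffers start at zero).  One iteration
nominally spans `dt = 0.016` s; `dt` is bookkeeping for time axes only —
all dynamics are expressed per iteration.  Updates are synchronous across
units (double-buffered: every unit reads previous-step values), so loops
close only through the environment.

Two equivalent-at-steady-state conventions exist for where the slowing
acts; we place the gain inside the leaky integrator (`Qo` relaxes toward
`Ko·e`).  Transient shapes differ between conventions; fixed points do
not.

With constant `r` and `D` the loop has the fixed point

    e* = (r − Ki·D) / (1 + Ki·Kf·Ko),

independent of `S` and `d`, which serves as the simulation oracle.
Stability of the discrete update is *not* free: the one-step coefficient
is `1 − (1 + Ki·Kf·Ko)/S`, so a loop is stable only when
`S > (1 + Ki·Kf·Ko)/2`; adding transport delay shrinks the stable region
further.  Randomized convergence tests draw parameters inside this
region (`S ≥ 0.7·(1 + loop gain)`).  Any signal exceeding `1e9` in
magnitude aborts with an instability error naming the step — divergence
is distinguished from legitimate oscillation, which stays bounded.

## Hierarchies

Units are grouped into levels.  A non-top unit's reference at step `t` is
the signed weighted sum of its superiors' outputs at `t − 1` (additive
combination — "relative weighting", not averaging); its perceptual input
is a signed weighted sum of lower-level perceptions, with level-0 units
perceiving an environment quantity.  Units with no superior carry fixed
references.  The data model supports any number of levels; the bundled
scenarios use at most three.

The canonical conflict architecture has one top unit whose output sends
two references (weights `w_tA`, `w_tB`) to two mid units; both mid units
perceive the low-level perception (weight 1) and jointly set the low
unit's reference (weights `w_A`, `w_B`); the top unit perceives the mean
of the mid perceptions.  When the implied mid references oppose, neither
mid error can reach zero: the low-level variable settles at a
gain-weighted compromise and chronic error persists — the structural
signature of goal conflict.

## Reorganization

Reorganization perturbs designated parameters (connection weights, or
optionally mid-level gains) by trial and error while error is sustained,
in the E. coli manner.  Every `window` iterations the root-mean-square
error across all units over that window is measured.  If it is at or
below `error_tolerance`, nothing changes (quiescence).  If it increased
since the last check, a fresh uniformly random unit direction is drawn
and the step size set to `step_coefficient ×` the *current* windowed
error (a tumble); otherwise the previous direction and step size persist
(a run).  The step is added to the targeted parameters, clipped to
`±clip_bound` (clipping is logged).

Two deliberate choices here:

* **Window statistic.** The windowed error fed to the learner is the
  RMS over the window (the same statistic as the WMRSE outcome metric),
  not the raw cumulative sum, so `step_coefficient` has a
  window-length-independent scale.
* **Step scaling.** The tumble step scales with the current error
  ("loss of control"), not with the error *increment*.  An
  increment-proportional step self-quenches on broad error plateaus —
  the increment is near zero while the error itself is still large, so
  exploration collapses far from any workable organization; we observed
  exactly this failure in development.  Error-proportional steps keep
  the search vigorous while control is poor and fine-grained as control
  is regained, and the proportionality `‖Δθ‖ = c·E` on tumbles is
  property-tested.

The outcome metric is the Window Mean Root Squared Error (WMRSE):
squared errors across all control units averaged over ten iteration
cycles, then square-rooted.  It is computed on a sliding window (stride
1) for test granularity; a strided variant (stride = window) is
available.

## The conflict-reorganization experiment

A cohort of random conflict agents is simulated under three paired
conditions: no reorganization, reorganization of the two mid→low
weights, and reorganization of the two top→mid weights.  Frozen
scenario defaults (chosen for discrete stability of all random draws and
effective search, then fixed):

| parameter | value | note |
|---|---|---|
| unit gains `Ko` (low/mid/top) | 20 / 3 / 3 | low loop `(1+Ko)/S < 2` |
| slowing `S` (all units) | 15 | transients settle well inside a window |
| output saturation | ±10 | bounded error for badly signed draws |
| top reference | 5 | arbitrary nonzero goal |
| weights | U(±[0.1, 1]) | dead zone 0.1: no vacuous connections |
| reorg window | 200 iterations | ≳ 10 closed-loop settling times |
| windows per run | 150 | 30 000 iterations per agent |
| step coefficient | 0.02 | typical tumble ~0.1 weight units |
| error tolerance | 0.5 | quiescence once control is regained |
| weight clip | ±8 | search box (library default ±100) |

The structural prediction is that top-level reorganization outperforms
mid-level: aligning `w_tA ≈ w_tB` removes the conflict at its source, so
near-zero error is attainable, whereas mid-level changes can only trade
off the irreducible spread `|w_tA − w_tB|·|Qo_top|` between errors.
Numerical scans of the attainable minima confirm this for most draws.
The demonstration default is 20 agents; the statistical replication uses
200 paired agents and one-sided sign tests (α = 0.01) on final WMRSE
(last 10 iterations), yielding median ordering top < mid < none.  A
whole condition runs as one vectorized ensemble; its arithmetic is
asserted (in tests) to agree with the general per-agent network
simulator to 1e-12.

## Two-agent conflict regimes

A one-dimensional reduction of the crowd-style two-agent demo.  Agent A
(start 0) controls its position toward a goal (10) and a one-sided
proximity defense (repelled, with weight 1 × its gain, when B is nearer
than 1.8).  Agent B (start 22) controls its proximity to A toward 1.2.
Outputs are proportional velocities (`rate = 0.02` per unit gain) capped
at 8 per iteration; bodies cannot overlap within radius 1.5 — the
contact correction displaces A by 30% of the overlap (a high-gain B
bulldozes).  Seeded jitter (±0.05) perturbs the starts.

Classification after 3000 iterations, thresholds documented as fractions
of the goal separation (10): `goals_met` if both final errors < 5% of
separation; `oscillation` if late-half variance of A's position > 10% of
separation²; else `blocked`.  With gain 0.5 for both, both goals are
met; with B at gain 150 and A at 0.5, B presses into contact and A ends
far from its goal (blocked); with both at 150 the discrete loops are
unstable (`rate·gain = 3 > 2`) and a wide bounded limit cycle results
(oscillation).  The regimes are a property of the documented geometry;
they are checked at fixed seeds.

## Approach–avoidance compromise

Two control systems hold opposing references for one distance variable —
a defensive system (reference `r_safe`, gain `g_safe`) and an approach
system (`r_approach < r_safe`, `g_approach`) — with *pure integrating*
outputs whose sum sets the distance.  The settled distance is the
gain-weighted virtual reference `(g_s·r_s + g_a·r_a)/(g_s + g_a)`,
independent of constant disturbances (the integrators absorb them), and
closer to the defensive distance when fear carries more gain.  The
update is stable for `rate·(g_s + g_a) < 2`; the implementation enforces
a 1.5 bound with a clear error.  Note the outputs themselves drift in
opposite directions without bound while the conflict persists — the
arms-race signature of unresolved conflict; runs are kept short of the
instability guard.

## Therapy-outcome cohort

Each simulated case carries a symptom score on the CORE-10 scale
(0–40, higher = more distress) across sessions (default 26, the
conventional dose–response horizon).  The reference for symptoms is
zero, so the score *is* the error.  Per session, a random change occurs
with probability `score/40` and magnitude drawn zero-mean Gaussian with
SD `0.5 × score`; scores clip to the scale and carry over between
sessions.  Improvement is not guaranteed on any step: the decelerating
mean curve emerges because exploration is error-tuned — high scores are
volatile, low scores sticky, so mass accumulates near zero.  An optional
deterministic improvement bias exists behind a config flag but defaults
off.  Baseline severities are drawn from a truncated normal (mean 20,
SD 7 on [0, 40]); the clinical cohort that motivated the default size
(5,613 cases) did not publish its severity distribution, so this stands
in as a realistic intake mix.

Pattern detectors are explicit config, not clinical doctrine: a *sudden
gain* at session `t` requires `score(t+1) ≤ score(t) − 6` with the mean
of the following 2 sessions staying below `score(t) − 3`; an *early
response* is a drop of ≥ 6 points below baseline within the first 4
post-intake sessions.  Trajectory summaries compare an exponential-decay
fit `a·e^(−bt) + c` against a straight line by RMSE on the cohort mean
curve; an all-constant cohort is reported with both RMSEs zero and a
degeneracy flag.

What the cohort generator does *not* emulate: measurement error in
CORE-10 scoring, dropout/missing sessions, therapist effects, or any
coupling between cases.  Passing tests show the reorganization-style
error-tuned exploration reproduces the qualitative trajectory shapes
(deceleration, early response, sudden gains), not that it fits any real
clinical dataset.

## Tracking-model fitting

Synthetic pursuit-tracking data are generated by a known model — either
one-level position control (`gain`, `slowing`, `delay`) or a two-level
hierarchy in which a proximity controller sets reference values for a
velocity controller (`gain1`, `slowing1`, `gain2`, `slowing2`, shared
`delay`) — tracking a predictable (sinusoid, amplitude 10, period 300)
or pseudorandom (uniform noise smoothed by a 20-iteration moving
average) target, with optional Gaussian observation noise.  The velocity
scale `kv = 0.1` is fixed, not fitted: it is jointly unidentifiable with
the gains.

Fitting is statsmodels-style (`TrackingModel(...).fit()` →
`FitResult`): the objective (cursor RMSE) is simulation-defined and
non-smooth in the delay, so continuous parameters are optimized by
Nelder–Mead from 8 seeded multistarts within documented bounds, with the
delay on an integer grid 0–3; diverging candidates are penalized rather
than raised.  Noiseless self-generated data are recovered essentially
exactly (delay exact, continuous parameters ≪ 1%); under observation
noise, identifiability of the slowing constant requires the pseudorandom
target — a single sinusoid excites one frequency and leaves `S` poorly
constrained.  Data generated by the two-level model on a sinusoid are
fit strictly better by the two-level model than by the one-level model;
both RMSE and correlation are reported since either fit statistic may be
of interest.

## Problem sizes and seeds

All randomness descends from explicit integer seeds (per-agent streams
are spawned deterministically from a base seed), and every scenario
rerun with the same config and seed is byte-identical in its artifacts.
The bundled studies run at 200 paired conflict agents, 1,000 therapy
cases (5,613 for the full default cohort), 100-draw oracle checks and
900-sample tracking fits — sizes at which the reported orderings and
tolerances are stable across seeds while a full run of every study
completes in about half a minute on one CPU.

## Known limitations

* Linear input/output functions only; no sensor noise inside loops.
* The conflict experiment's vectorized ensemble is specialized to the
  fixed four-unit topology (the general simulator handles arbitrary
  adjacent-level networks, but more slowly).
* The two-agent demo's regime boundaries are tied to its documented
  geometry; it illustrates gain-dependent conflict, it is not a crowd
  model.
* Reorganization targets are the conflict architecture's four weights
  (or mid gains); arbitrary parameter sets would need a thin adapter.
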