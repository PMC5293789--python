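# Methods

## Model

The package implements the reduced two-population winner-take-all
(WTA) rate model with slow NMDAR gating dynamics in its current-mode
form.  State: two dimensionless gating variables `S1, S2`, the average
open fractions of NMDA-receptor channels at the two populations'
recurrent synapses.  Dynamics:

    C·U_T · dS_i/dt = −I_τ·S_i + (1 − S_i)·(I_γ/I_ref)·I_r,i
    I_syn,i = I_w+·S_i − I_w−·S_j + I_0 + I_sti,i          (j ≠ i)
    I_r,i   = x_i / (1 − exp(−g·x_i)),  x_i = (I_gain^r/I_ref^r)·I_syn,i − I_thr^r

Assumptions inherited from the reduction: all fast synaptic and
membrane variables are slaved to the slow NMDA gating (time constant
C·U_T/I_τ = 0.1 s at the defaults); firing is a static function of
synaptic current; the two populations are symmetric in parameters; the
system is noise free.  A `rectify_synapse` option clamps each
synaptic current at zero from below, mimicking the rectifier-like
behavior of an analog synaptic-current circuit; it is off by default
and excluded from differentiable analysis paths only when the clamp is
active at the evaluation point.

The hard rectifier activation `max(x, 0)` is retained for comparison
and for the g → ∞ limit checks, but all phase-plane analysis uses the
smooth activation, which is strictly positive and C¹; its removable
singularity at x = 0 (value 1/g) is evaluated by a series branch for
|g·x| < 1e−8, and the far-sub-threshold tail by the asymptotic form
−x·e^{g·x} to avoid overflow.

## Units

Currents pA, capacitance pF, voltage mV, time s.  C·U_T is then in pC
(20 pF × 25 mV = 0.5 pC) and pC/pA = s, so no conversion constants
appear anywhere.  The activation smoothness g = 0.2 is interpreted
per pA, applied to the drive x expressed in pA.

## Parameters

Defaults (all overridable per run): I_τ = 5, I_γ = 10, I_ref = 100,
I_gain^r = 100, I_thr^r = 50, I_ref^r = 100, I_0 = 15 pA; C = 20 pF,
U_T = 25 mV, g = 0.2 /pA.  The recurrent weights have no defaults and
must be supplied; the weight sets exercised throughout the tests are
I_w− = 60 pA with I_w+ = 100 pA (decision), 200 / 250 pA (working
memory) and 120 / 100 / 80 pA (hysteresis).  I_w− is only specified
for the decision configuration; the same 60 pA is carried to the other
tasks and exposed as a knob.

## Study configurations

The attractor regime depends jointly on I_w+ and the stimulus
strength.  Two regime placements are fixed package-wide and used by
the tests and the acceptance script:

* **Decision (competition) regime: 40 pA unbiased amplitude.**  At the
  decision weights (100/60 pA) the unbiased-stimulus bifurcation
  diagram shows the symmetric state destabilizing between roughly 28
  and 57 pA, producing a saddle plus two winner attractors.  The
  printed 15 pA amplitude leaves the model mono-stable with winner
  activity far below the 50 pA decision threshold (a consequence of
  the admittedly imprecise mapping between the analog circuit and the
  model parameter set), so reaction-time experiments are run at 40 pA,
  inside the competition window, where the winner's activity
  (≈59 pA) crosses the printed 50 pA threshold.  `run_decision`
  defaults remain the printed protocol values.

* **Hysteresis regime: 28 pA ramp amplitude.**  Asymmetric (winner)
  branches at unbiased stimulus exist only for
  I_w+ ≳ 133 pA at 15 pA amplitude (from the steady-state quadratic of
  the hard-activation limit), so the printed 15 pA ramp produces no
  coherence-interval bistability at the hysteresis weight set.  At
  28 pA the structure is exactly the described one: the bistable
  coherence interval at I_w+ = 120 pA contains Coh = 0, the interval
  at 100 pA lies strictly inside it, and at 80 pA it is empty.  The
  ramp duration default stays at the printed T = 20 s; structural
  loop-width measurements use slow ramps (T = 160–640 s), because the
  escape from a just-destroyed fold lags the ramp by
  O((dCoh/dt)^{2/3}) and only the slow-ramp limit tracks the fold
  positions.

## Task protocols

* **Decision**: start at the zero-stimulus spontaneous state; apply
  (A·(1+Coh), A·(1−Coh)) from t = 0; reaction time is the first
  linear-interpolated crossing of either firing activity through the
  threshold (default 50 pA).  At Coh = 0 the noise-free symmetric
  system never decides — by design.
* **Working memory**: pre-cue 0.5 s, cue 1.0 s, delay 3.0 s (5–30
  gating time constants each, long enough for trajectories to settle;
  cue/delay durations are not dictated by the protocol and are
  configurable).  Cue currents: 70 pA one-sided (load 1) or 50 pA to
  both (load 2).  "Retained" is structural, not a rate cut-off: the
  end-of-delay state is settled under zero stimulus and matched
  (1e−3 max-norm) against the zero-stimulus fixed-point list; a
  population counts as retained iff the matched attractor holds its
  gating value at least 0.1 above the spontaneous level.
* **Hysteresis**: coherence ramps linearly +1 → −1 over [0, T]
  (reversed for the reverse direction) at constant amplitude; the
  stimulus components cross at T/2 by construction.  The percept
  switch is the firing-activity crossover (1e−9 pA dead band,
  linear interpolation); the loop width is |Coh at forward crossover|
  + |Coh at reverse crossover|.

## Numerics

* **Integration**: fixed-step classical RK4 (default dt = 1 ms,
  ≥ 100 steps per time constant; 2–5 ms for multi-hundred-second
  ramps, still ≥ 20 steps per time constant), forward Euler retained
  for cross-checks.  The unit square is forward invariant under the
  exact flow (dS_i/dt ≥ 0 at S_i = 0, < 0 at S_i = 1 for non-negative
  stimuli), so no state clipping is applied.  Endpoint changes under
  dt halving are < 1e−6.
* **Fixed points**: damped Newton (backtracking by halving, ≤ 30
  halvings) with the analytic Jacobian from a 25×25 seed grid,
  polished to residual < 1e−9 /s, deduplicated at 1e−4 max-norm —
  root separations in every configuration studied exceed 1e−2.
  Diverging seeds are discarded; completeness is guarded by an
  independent brute-force oracle (`grid_scan_fixed_points`): n×n
  cells, cells where both field components change sign are clustered
  (8-connectivity) and refined by backtracking bisection; counts are
  stable across n ∈ {200, 400, 800}.
* **Stability**: eigenvalues of the analytic Jacobian (verified
  against central finite differences to ~1e−10 relative); points with
  |Re λ| < 1e−12 /s raise a marginal-stability error instead of being
  silently classified; bifurcation sweeps record such values with a
  flag.
* **Analysis domain**: [0,1]².  Steady states necessarily satisfy
  S ∈ [0,1) because the smooth activation is strictly positive;
  negative-S regions sometimes drawn in phase-plane figures are a
  visualization device only.
* **Bifurcation sweeps** are grid-based (full fixed-point recomputation
  per value) rather than pseudo-arclength continuation — 2-D root
  finding is cheap and the regimes involve only equilibria.  The
  bistable-interval edges are refined by bisection to 1e−3 in Coh.
* **Saddle time constants**: the symmetric fixed point is located by
  1-D bracketing/bisection on the diagonal; 1/Re λ+ agrees within 5%
  with the e-folding time fitted to the divergence of two trajectories
  straddling the diagonal.

## Problem sizes

The shipped test-suite and acceptance-script sizes: 25×25 Newton
seeds; grid-scan oracle at n = 200–400 (n = 800 in spot checks);
coherence sweeps at step 0.02 over [−0.4, 0.4] or [−0.6, 0.6];
unbiased-stimulus sweeps at step 5 pA over [0, 100]; reaction times
over five coherence levels 0.032–0.512; hysteresis ramps at
T = 20–640 s.  These sizes keep every reported quantity stable at the
quoted tolerances.

## Limitations

* The model-to-analog-circuit parameter mapping is imprecise by the
  source's own account; circuit-level magnitudes (specific reaction
  times, the circuit's 15.5 s crossover) are out of scope.  The
  package reproduces the model-side structures and the qualitative
  behaviors.
* Deterministic and noise free: no psychometric choice probabilities,
  no stochastic reaction-time distributions.
* Two populations only; no Hopf/limit-cycle machinery (all regimes
  studied involve equilibria only); basin boundaries are probed
  empirically by settling, not traced as separatrices.
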