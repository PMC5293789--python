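"""Cognitive-task drivers: decision-making, working memory, hysteresis.

Each driver wraps the integrator with the task's stimulus protocol and
extracts the behavioral metric the task is scored on:

* decision   — reaction time: first crossing of a firing-activity
               threshold after stimulus onset, and the winning
               population;
* working memory — how many cued items persist as elevated activity
               through the delay (memory capacity);
* hysteresis — lag between the stimulus crossover and the activity
               crossover under a slowly ramped coherence, and the
               width of the perceptual hysteresis loop in Coh units.

The model is deterministic (noise free); at exactly zero coherence a
symmetric start never breaks symmetry and no decision is made.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    ModelParams,
    State,
    StimulusSample,
    ZERO_STIMULUS,
    decision_stimulus,
    hysteresis_coherence,
)
from .phaseplane import find_fixed_points
from .simulate import (
    StimulusProtocol,
    Trajectory,
    detect_activity_crossover,
    detect_threshold_crossing,
    integrate,
    settle_to_attractor,
    spontaneous_state,
)

__all__ = [
    "DecisionOutcome",
    "WMOutcome",
    "HysteresisOutcome",
    "run_decision",
    "run_wm",
    "memory_capacity",
    "run_hysteresis",
    "hysteresis_strength_sweep",
]

# A population counts as "retained" if its attractor gating value sits at
# least this far above the spontaneous symmetric level.
MEMORY_MARGIN = 0.1
# Max-norm tolerance for matching a settled state to a fixed point.
MATCH_TOL = 1e-3


@dataclass
class DecisionOutcome:
    winner: int | None          # 1, 2 or None
    reaction_time: float | None  # s from stimulus onset
    trajectory: Trajectory

    def to_dict(self) -> dict:
        return {"winner": self.winner, "reaction_time_s": self.reaction_time}


@dataclass
class WMOutcome:
    load: int
    retained: int
    trajectory: Trajectory

    def to_dict(self) -> dict:
        return {"load": self.load, "retained": self.retained}


@dataclass
class HysteresisOutcome:
    stimulus_crossover_time: float
    activity_crossover_time: float | None
    lag: float | None
    crossover_coherence: float | None  # signed Coh at the activity crossover
    loop_width: float | None           # |Coh_fwd| + |Coh_rev|, filled by sweeps
    trajectory: Trajectory

    def to_dict(self) -> dict:
        return {
            "stimulus_crossover_time_s": self.stimulus_crossover_time,
            "activity_crossover_time_s": self.activity_crossover_time,
            "lag_s": self.lag,
            "crossover_coherence": self.crossover_coherence,
            "loop_width": self.loop_width,
        }


# ---------------------------------------------------------------------------
# Decision making
# ---------------------------------------------------------------------------

def run_decision(params: ModelParams, coherence: float,
                 amplitude: float = 15.0, threshold: float = 50.0,
                 t_max: float = 5.0, dt: float = 1e-3) -> DecisionOutcome:
    """Two-alternative decision trial.

    Starts at the spontaneous (zero-stimulus) state; the random-dot
    stimulus (amplitude*(1±Coh)) switches on at t = 0.  The reaction
    time is the first crossing of either firing activity through
    ``threshold`` (pA); the winner is the crossing population.  Whether
    the threshold is reachable depends on the configuration: the
    stimulus must place the system in a competition (WTA) regime.
    """
    if abs(coherence) > 1:
        raise ValueError(f"|coherence| must be <= 1, got {coherence}")
    start = spontaneous_state(params)
    stim = decision_stimulus(amplitude, coherence)
    protocol = StimulusProtocol.constant(stim, t_max)
    traj = integrate(params, protocol, start, dt=dt)
    hit = detect_threshold_crossing(traj, threshold, after=0.0)
    if hit is None:
        return DecisionOutcome(None, None, traj)
    pop, t_cross = hit
    return DecisionOutcome(pop, t_cross, traj)


# ---------------------------------------------------------------------------
# Working memory
# ---------------------------------------------------------------------------

def run_wm(params: ModelParams, load: int, cue_duration: float = 1.0,
           delay_duration: float = 3.0, pre_duration: float = 0.5,
           cue_one: float = 70.0, cue_two: float = 50.0,
           dt: float = 1e-3) -> WMOutcome:
    """Delayed-response trial: pre-cue (no stimulus), cue, delay.

    Load 1 cues one population at ``cue_one`` pA; load 2 cues both at
    ``cue_two`` pA.  A population is retained when the end-of-delay
    state, settled under zero stimulus, matches a zero-stimulus
    attractor whose gating value for that population exceeds the
    spontaneous level by at least 0.1 — a structural criterion (basin
    membership) rather than a rate cut-off.
    """
    if load not in (1, 2):
        raise ValueError(f"load must be 1 or 2, got {load}")
    cue = StimulusSample(cue_one, 0.0) if load == 1 else StimulusSample(cue_two, cue_two)
    start = spontaneous_state(params)
    protocol = StimulusProtocol.stages([
        (pre_duration, ZERO_STIMULUS),
        (cue_duration, cue),
        (delay_duration, ZERO_STIMULUS),
    ])
    traj = integrate(params, protocol, start, dt=dt)
    retained = _count_retained(params, traj.final_state(), start)
    return WMOutcome(load, retained, traj)


def _count_retained(params: ModelParams, end_state: State, spont: State) -> int:
    settled = settle_to_attractor(params, ZERO_STIMULUS, end_state).state
    fps = find_fixed_points(params, ZERO_STIMULUS)
    matched = None
    for fp in fps:
        if (abs(fp.state.S1 - settled.S1) < MATCH_TOL
                and abs(fp.state.S2 - settled.S2) < MATCH_TOL):
            matched = fp
            break
    if matched is None or not matched.stable:
        return 0
    base = max(spont.S1, spont.S2)
    retained = 0
    if matched.state.S1 >= base + MEMORY_MARGIN:
        retained += 1
    if matched.state.S2 >= base + MEMORY_MARGIN:
        retained += 1
    return retained


def memory_capacity(params: ModelParams, **wm_kwargs) -> int:
    """Largest load in {1, 2} for which every cued item is retained
    through the delay; 0 if even a single item is lost."""
    capacity = 0
    for load in (1, 2):
        outcome = run_wm(params, load, **wm_kwargs)
        if outcome.retained == load:
            capacity = load
        else:
            break
    return capacity


# ---------------------------------------------------------------------------
# Hysteresis in visual perception
# ---------------------------------------------------------------------------

def run_hysteresis(params: ModelParams, T: float = 20.0,
                   amplitude: float = 15.0, direction: str = "forward",
                   dt: float = 1e-3) -> HysteresisOutcome:
    """Ramped-coherence discrimination trial.

    Coherence ramps linearly from +1 to -1 over [0, T] (forward), or
    from -1 to +1 (reverse); the two stimulus components cross at
    t = T/2 by construction.  The perceptual switch is the activity
    crossover; its signed coherence measures how far past the stimulus
    crossover the previous percept survives.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    if direction not in ("forward", "reverse"):
        raise ValueError(f"direction must be 'forward' or 'reverse', got {direction!r}")
    sign = 1.0 if direction == "forward" else -1.0

    def gen(t: float) -> StimulusSample:
        coh = sign * hysteresis_coherence(min(max(t, 0.0), T), T)
        return decision_stimulus(amplitude, coh)

    start = spontaneous_state(params)
    protocol = StimulusProtocol(((0.0, T, gen),))
    traj = integrate(params, protocol, start, dt=dt)
    t_stim = T / 2.0
    # Ignore crossings while both populations sit at the (symmetric)
    # spontaneous level right at onset.
    t_act = detect_activity_crossover(traj, after=min(0.05 * T, 1.0))
    if t_act is None:
        return HysteresisOutcome(t_stim, None, None, None, None, traj)
    coh_at_cross = sign * hysteresis_coherence(min(t_act, T), T)
    return HysteresisOutcome(t_stim, t_act, t_act - t_stim, coh_at_cross, None, traj)


def hysteresis_loop_width(params: ModelParams, T: float = 20.0,
                          amplitude: float = 15.0, dt: float = 1e-3):
    """Loop width |Coh_fwd| + |Coh_rev| from a forward and a reverse
    ramp; 0.0 when either direction shows no crossover."""
    fwd = run_hysteresis(params, T, amplitude, "forward", dt)
    rev = run_hysteresis(params, T, amplitude, "reverse", dt)
    if fwd.crossover_coherence is None or rev.crossover_coherence is None:
        return 0.0, fwd, rev
    width = abs(fwd.crossover_coherence) + abs(rev.crossover_coherence)
    fwd.loop_width = width
    rev.loop_width = width
    return width, fwd, rev


def hysteresis_strength_sweep(params: ModelParams, iw_plus_values,
                              T: float = 20.0, amplitude: float = 15.0,
                              dt: float = 1e-3) -> list[float]:
    """Hysteresis loop width for each self-excitation strength, in the
    order given."""
    if len(iw_plus_values) < 2:
        raise ValueError("need at least 2 I_w_plus values")
    widths = []
    for wp in iw_plus_values:
        width, _, _ = hysteresis_loop_width(params.replace(I_w_plus=float(wp)),
                                            T, amplitude, dt)
        widths.append(width)
    return widths
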