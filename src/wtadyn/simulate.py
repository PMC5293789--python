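"""Time integration of the two-variable WTA system under piecewise stimuli.

Fixed-step explicit integration (classical RK4 by default, forward
Euler for cross-checking).  The system is smooth and non-stiff with a
single slow time scale tau = C*U_T/I_tau (0.1 s at the printed
defaults); dt = 1 ms gives >= 100 steps per time constant.  The model
is noise free: there is no RNG anywhere in the dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .model import (
    ModelParams,
    State,
    StimulusSample,
    ZERO_STIMULUS,
    field_scalar,
    firing_rates,
    synaptic_currents,
)

__all__ = [
    "StimulusProtocol",
    "Trajectory",
    "IntegrationError",
    "integrate",
    "detect_threshold_crossing",
    "detect_activity_crossover",
    "settle_to_attractor",
    "SettleResult",
]

# Dead band (pA) below which an activity difference counts as zero when
# looking for sign changes; suppresses spurious flips from rounding.
CROSSOVER_DEAD_BAND = 1e-9


class IntegrationError(RuntimeError):
    """Raised when the state becomes non-finite during integration."""


@dataclass(frozen=True)
class StimulusProtocol:
    """Piecewise-in-time stimulus: contiguous (t_start, t_end, generator)
    segments covering [0, duration].  Each generator maps a time in
    seconds to a StimulusSample."""

    segments: tuple[tuple[float, float, Callable[[float], StimulusSample]], ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        t = 0.0
        for t0, t1, _gen in self.segments:
            if abs(t0 - t) > 1e-12:
                raise ValueError(f"segments must be contiguous from 0; gap/overlap at t={t0}")
            if t1 <= t0:
                raise ValueError(f"segment ({t0}, {t1}) has non-positive length")
            t = t1

    @property
    def duration(self) -> float:
        return self.segments[-1][1]

    def sample(self, t: float) -> StimulusSample:
        """Stimulus at time t (last segment owns its right endpoint)."""
        for t0, t1, gen in self.segments:
            if t < t1 or t1 == self.duration:
                return gen(t)
        raise ValueError(f"t={t} outside protocol [0, {self.duration}]")

    @classmethod
    def constant(cls, stim: StimulusSample, duration: float) -> "StimulusProtocol":
        return cls(((0.0, duration, lambda t, s=stim: s),))

    @classmethod
    def stages(cls, stages: Sequence[tuple[float, StimulusSample]]) -> "StimulusProtocol":
        """Build from (duration, constant stimulus) stages."""
        segs = []
        t = 0.0
        for dur, stim in stages:
            segs.append((t, t + dur, lambda _t, s=stim: s))
            t += dur
        return cls(tuple(segs))


@dataclass
class Trajectory:
    """Sampled time course: gating variables, firing activities and
    synaptic currents.  Units: s, dimensionless, pA."""

    times: np.ndarray
    S1: np.ndarray
    S2: np.ndarray
    I_r1: np.ndarray
    I_r2: np.ndarray
    I_syn1: np.ndarray
    I_syn2: np.ndarray

    def final_state(self) -> State:
        return State(float(self.S1[-1]), float(self.S2[-1]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": self.times, "S1": self.S1, "S2": self.S2,
            "Ir1": self.I_r1, "Ir2": self.I_r2,
            "Isyn1": self.I_syn1, "Isyn2": self.I_syn2,
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Trajectory":
        df = pd.read_csv(path)
        return cls(df["t"].to_numpy(), df["S1"].to_numpy(), df["S2"].to_numpy(),
                   df["Ir1"].to_numpy(), df["Ir2"].to_numpy(),
                   df["Isyn1"].to_numpy(), df["Isyn2"].to_numpy())


def _derived_currents(params: ModelParams, S1, S2, stims):
    c1 = np.array([s.I_sti_1 for s in stims])
    c2 = np.array([s.I_sti_2 for s in stims])
    i1, i2 = synaptic_currents(params, (S1, S2), (c1, c2))
    r1, r2 = firing_rates(params, (S1, S2), (c1, c2))
    return r1, r2, i1, i2


def integrate(params: ModelParams, protocol: StimulusProtocol, initial: State,
              dt: float = 1e-3, method: str = "rk4") -> Trajectory:
    """Integrate the WTA dynamics over a stimulus protocol.

    Fixed step ``dt``; each segment is sampled with round(len/dt) steps
    so segment boundaries coincide with sample times.  [0,1]^2 is
    forward invariant under the dynamics, so no clipping is applied.

    Raises
    ------
    IntegrationError
        If the state becomes non-finite (names the failure time).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if method not in ("euler", "rk4"):
        raise ValueError(f"method must be 'euler' or 'rk4', got {method!r}")

    times = [0.0]
    s1, s2 = float(initial.S1), float(initial.S2)
    out_s1 = [s1]
    out_s2 = [s2]
    stims = [protocol.sample(0.0)]

    for t0, t1, gen in protocol.segments:
        n = max(1, int(round((t1 - t0) / dt)))
        h = (t1 - t0) / n
        for k in range(n):
            t = t0 + k * h
            stim_t = gen(t)
            c1, c2 = stim_t.I_sti_1, stim_t.I_sti_2
            if method == "euler":
                f1, f2 = field_scalar(params, s1, s2, c1, c2)
                s1 += h * f1
                s2 += h * f2
            else:
                mid = gen(t + h / 2.0)
                end = gen(t + h)
                a1, a2 = field_scalar(params, s1, s2, c1, c2)
                b1, b2 = field_scalar(params, s1 + h / 2 * a1, s2 + h / 2 * a2,
                                      mid.I_sti_1, mid.I_sti_2)
                g1, g2 = field_scalar(params, s1 + h / 2 * b1, s2 + h / 2 * b2,
                                      mid.I_sti_1, mid.I_sti_2)
                d1, d2 = field_scalar(params, s1 + h * g1, s2 + h * g2,
                                      end.I_sti_1, end.I_sti_2)
                s1 += h / 6.0 * (a1 + 2 * b1 + 2 * g1 + d1)
                s2 += h / 6.0 * (a2 + 2 * b2 + 2 * g2 + d2)
            t_next = t0 + (k + 1) * h
            if not (np.isfinite(s1) and np.isfinite(s2)):
                raise IntegrationError(f"non-finite state at t={t_next:.6g} s")
            times.append(t_next)
            out_s1.append(s1)
            out_s2.append(s2)
            stims.append(gen(t_next) if t_next < t1 else protocol.sample(t_next))

    times = np.array(times)
    S1 = np.array(out_s1)
    S2 = np.array(out_s2)
    r1, r2, i1, i2 = _derived_currents(params, S1, S2, stims)
    return Trajectory(times, S1, S2, r1, r2, i1, i2)


def detect_threshold_crossing(traj: Trajectory, threshold: float,
                              after: float = 0.0):
    """First upward crossing of either firing activity through ``threshold``.

    Returns (population id 1|2, crossing time s) with linear
    interpolation between samples, or None if no crossing at/after
    ``after``.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    t = traj.times
    best = None
    for pop, ir in ((1, traj.I_r1), (2, traj.I_r2)):
        below = ir[:-1] < threshold
        above = ir[1:] >= threshold
        idx = np.where(below & above & (t[1:] >= after))[0]
        for k in idx:
            tc = t[k] + (t[k + 1] - t[k]) * (threshold - ir[k]) / (ir[k + 1] - ir[k])
            if tc >= after and (best is None or tc < best[1]):
                best = (pop, float(tc))
            break
    return best


def detect_activity_crossover(traj: Trajectory, after: float = 0.0):
    """First time at/after ``after`` where sign(I_r1 - I_r2) changes,
    linearly interpolated; differences inside a 1e-9 pA dead band are
    treated as zero.  Returns the time in seconds, or None."""
    t = traj.times
    d = traj.I_r1 - traj.I_r2
    d = np.where(np.abs(d) < CROSSOVER_DEAD_BAND, 0.0, d)
    sgn = np.sign(d)
    # Compress out zero samples so a touch of the dead band still counts
    # as a crossing when the sign differs on either side of it.
    nz = np.where(sgn != 0)[0]
    if len(nz) < 2:
        return None
    flips = sgn[nz[:-1]] * sgn[nz[1:]] < 0
    for m in np.where(flips)[0]:
        i, j = nz[m], nz[m + 1]
        tc = t[i] + (t[j] - t[i]) * d[i] / (d[i] - d[j])
        if tc >= after:
            return float(tc)
    return None


@dataclass(frozen=True)
class SettleResult:
    state: State
    settled: bool


def settle_to_attractor(params: ModelParams, stim: StimulusSample,
                        initial: State, tol: float = 1e-8,
                        t_max: float = 60.0, dt: float = 1e-3) -> SettleResult:
    """Integrate under a constant stimulus until ||dS/dt||_inf < tol (1/s)
    or t_max seconds of model time; returns the final state with a
    settled flag."""
    s1, s2 = float(initial.S1), float(initial.S2)
    c1, c2 = stim.I_sti_1, stim.I_sti_2
    t = 0.0
    chunk = 0.1
    while t < t_max:
        n = int(round(chunk / dt))
        for _ in range(n):
            a1, a2 = field_scalar(params, s1, s2, c1, c2)
            b1, b2 = field_scalar(params, s1 + dt / 2 * a1, s2 + dt / 2 * a2, c1, c2)
            g1, g2 = field_scalar(params, s1 + dt / 2 * b1, s2 + dt / 2 * b2, c1, c2)
            d1, d2 = field_scalar(params, s1 + dt * g1, s2 + dt * g2, c1, c2)
            s1 += dt / 6.0 * (a1 + 2 * b1 + 2 * g1 + d1)
            s2 += dt / 6.0 * (a2 + 2 * b2 + 2 * g2 + d2)
        t += chunk
        f1, f2 = field_scalar(params, s1, s2, c1, c2)
        if max(abs(f1), abs(f2)) < tol:
            return SettleResult(State(s1, s2), True)
    return SettleResult(State(s1, s2), False)


def spontaneous_state(params: ModelParams) -> State:
    """Zero-stimulus resting state reached from the origin."""
    return settle_to_attractor(params, ZERO_STIMULUS, State(0.0, 0.0)).state
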