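"""Current-mode two-variable winner-take-all (WTA) attractor model.

Two neural populations compete through self-excitation and mutual
inhibition.  Each population is reduced to a single slow variable
``S_i`` — the average fraction of open NMDA-receptor channels at its
recurrent synapses — expressed in current mode as a ratio of circuit
currents ``S_i = I_{S,i} / I_ref``.  The gating variable obeys

    C*U_T * dS_i/dt = -I_tau*S_i + (1 - S_i) * (I_gamma/I_ref) * I_r,i

where ``I_r,i`` is the population firing activity (a current, pA)
produced by a linear-threshold unit driven by the total synaptic
current

    I_syn,i = I_w_plus*S_i - I_w_minus*S_j + I_0 + I_sti,i   (j != i).

Unit system: currents in pA, capacitance in pF, voltage in mV, time in
seconds.  The charge scale C*U_T is then in pC (1 pC / 1 pA = 1 s), so
the printed defaults give a gating time constant C*U_T/I_tau = 0.1 s
without any conversion constants.
"""

from __future__ import annotations

import json
import math
import tomllib
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable

import numpy as np

__all__ = [
    "ModelParams",
    "State",
    "StimulusSample",
    "gating_steady_state",
    "gating_time_constant",
    "rate_hard",
    "rate_smooth",
    "rate_smooth_derivative",
    "synaptic_currents",
    "firing_rates",
    "vector_field",
    "decision_stimulus",
    "hysteresis_coherence",
]

# Fields that must be strictly positive when given.
_POSITIVE_FIELDS = (
    "I_tau", "I_gamma", "I_ref", "I_gain_r", "I_thr_r", "I_ref_r",
    "I_0", "C", "U_T", "g",
)


@dataclass(frozen=True)
class ModelParams:
    """All bias currents and physical constants of the WTA model.

    The recurrent weights ``I_w_plus`` (self-excitation) and
    ``I_w_minus`` (mutual inhibition) are task specific and have no
    defaults; everything else defaults to the printed configuration.

    Parameters
    ----------
    I_tau : float
        Gating leak bias current, pA.  Sets the decay rate of S.
    I_gamma : float
        Gating drive bias current, pA.  Scales the opening rate.
    I_ref : float
        Reference current of the current-mode normalisation, pA.
    I_gain_r, I_thr_r, I_ref_r : float
        Gain, threshold and reference currents of the linear-threshold
        activation, pA.  The dimensionless gain is I_gain_r/I_ref_r and
        the firing threshold sits at I_syn = I_thr_r * I_ref_r/I_gain_r.
    I_0 : float
        Effective background synaptic input, pA.
    I_w_plus, I_w_minus : float
        Recurrent self-excitation and mutual-inhibition currents per
        unit gating variable, pA.
    C : float
        Gating capacitance, pF.
    U_T : float
        Thermal voltage, mV.
    g : float
        Smoothness of the soft activation, 1/pA.  Larger g approaches
        the hard rectifier.
    activation : {"smooth", "hard"}
        Which activation the dynamics use.  Phase-plane analysis
        requires "smooth" (differentiable).
    rectify_synapse : bool
        If True, clamp each synaptic current at 0 from below,
        mimicking the rectifier-like deviation of the analog synaptic
        current block.
    """

    I_w_plus: float
    I_w_minus: float
    I_tau: float = 5.0
    I_gamma: float = 10.0
    I_ref: float = 100.0
    I_gain_r: float = 100.0
    I_thr_r: float = 50.0
    I_ref_r: float = 100.0
    I_0: float = 15.0
    C: float = 20.0
    U_T: float = 25.0
    g: float = 0.2
    activation: str = "smooth"
    rectify_synapse: bool = False

    def __post_init__(self) -> None:
        for name in _POSITIVE_FIELDS:
            value = getattr(self, name)
            if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
                raise ValueError(f"{name} must be a strictly positive finite number, got {value!r}")
        for name in ("I_w_plus", "I_w_minus"):
            value = getattr(self, name)
            if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
                raise ValueError(f"{name} is task specific and must be supplied as a positive current (pA), got {value!r}")
        if self.activation not in ("smooth", "hard"):
            raise ValueError(f"activation must be 'smooth' or 'hard', got {self.activation!r}")

    # -- derived scales -------------------------------------------------

    @property
    def charge_pC(self) -> float:
        """C*U_T in pC (pF * mV / 1000)."""
        return self.C * self.U_T / 1000.0

    @property
    def gain(self) -> float:
        """Dimensionless activation gain I_gain_r / I_ref_r."""
        return self.I_gain_r / self.I_ref_r

    @property
    def kappa(self) -> float:
        """Dimensionless gating drive ratio I_gamma / I_ref."""
        return self.I_gamma / self.I_ref

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, data: dict) -> "ModelParams":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown ModelParams keys: {sorted(unknown)}")
        return cls(**data)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "ModelParams":
        """Load from a flat TOML or JSON key-value file (by extension)."""
        path = Path(path)
        if path.suffix == ".toml":
            data = tomllib.loads(path.read_text())
        else:
            data = json.loads(path.read_text())
        return cls.from_dict(data)

    def replace(self, **changes) -> "ModelParams":
        return replace(self, **changes)


@dataclass(frozen=True)
class State:
    """Pair of dimensionless NMDAR gating variables, each in [0, 1]."""

    S1: float
    S2: float

    def __iter__(self):
        return iter((self.S1, self.S2))

    def swapped(self) -> "State":
        return State(self.S2, self.S1)

    def as_array(self) -> np.ndarray:
        return np.array([self.S1, self.S2], dtype=float)


@dataclass(frozen=True)
class StimulusSample:
    """External sensory stimulus currents to the two populations, pA."""

    I_sti_1: float
    I_sti_2: float

    def __post_init__(self) -> None:
        if self.I_sti_1 < 0 or self.I_sti_2 < 0:
            raise ValueError(f"stimulus currents must be non-negative, got ({self.I_sti_1}, {self.I_sti_2})")

    def __iter__(self):
        return iter((self.I_sti_1, self.I_sti_2))

    def swapped(self) -> "StimulusSample":
        return StimulusSample(self.I_sti_2, self.I_sti_1)


ZERO_STIMULUS = StimulusSample(0.0, 0.0)


# ---------------------------------------------------------------------------
# Gating kinetics
# ---------------------------------------------------------------------------

def gating_steady_state(params: ModelParams, I_r: float | np.ndarray):
    """Steady-state gating value for a constant firing activity I_r (pA).

    S_bar = (I_gamma/I_ref * I_r) / (I_tau + I_gamma/I_ref * I_r),
    a saturating function in [0, 1).
    """
    I_r = np.asarray(I_r, dtype=float)
    if np.any(I_r < 0):
        raise ValueError("I_r must be non-negative")
    drive = params.kappa * I_r
    out = drive / (params.I_tau + drive)
    return float(out) if out.ndim == 0 else out


def gating_time_constant(params: ModelParams) -> float:
    """Gating time constant tau = C*U_T / I_tau in seconds.

    Independent of I_gamma and of the firing activity.
    """
    return params.charge_pC / params.I_tau


# ---------------------------------------------------------------------------
# Activation (linear-threshold unit and its smooth variant)
# ---------------------------------------------------------------------------

def _drive(params: ModelParams, I_syn):
    """Supra-threshold drive x = gain * I_syn - I_thr_r (pA)."""
    return params.gain * np.asarray(I_syn, dtype=float) - params.I_thr_r


def rate_hard(params: ModelParams, I_syn: float | np.ndarray):
    """Hard linear-threshold activation: max(gain*I_syn - I_thr_r, 0), pA."""
    out = np.maximum(_drive(params, I_syn), 0.0)
    return float(out) if out.ndim == 0 else out


def rate_smooth(params: ModelParams, I_syn: float | np.ndarray):
    """Softened linear-threshold activation x / (1 - exp(-g*x)), pA.

    Strictly positive for all finite inputs; the removable singularity
    at x = 0 evaluates to 1/g.  Near zero the series
    (1/g) * (1 + g*x/2 + (g*x)^2/12) is used; far below threshold the
    asymptotic form -x*exp(g*x) avoids overflow in exp.
    """
    x = _drive(params, I_syn)
    return _rate_smooth_from_drive(x, params.g)


def _rate_smooth_from_drive(x, g: float):
    x = np.asarray(x, dtype=float)
    u = g * x
    small = np.abs(u) < 1e-8
    deep = u < -500.0
    u_safe = np.where(small | deep, 1.0, u)
    x_safe = np.where(small | deep, 1.0, x)
    with np.errstate(over="ignore"):
        main = x_safe / (-np.expm1(-u_safe))
    series = (1.0 / g) * (1.0 + u / 2.0 + u * u / 12.0)
    deep_val = -x * np.exp(np.where(deep, np.maximum(u, -745.0), -745.0))
    out = np.where(small, series, np.where(deep, deep_val, main))
    return float(out) if out.ndim == 0 else out


def rate_smooth_derivative(params: ModelParams, I_syn: float | np.ndarray):
    """d(rate_smooth)/d(I_syn): chain rule through the drive (dimensionless).

    d/dx [x/(1-e^{-u})] with u = g*x equals
    (1 - (1+u) e^{-u}) / (1 - e^{-u})^2; near u=0 the series
    1/2 + u/6 is used, and the derivative decays to 0 deep below
    threshold.
    """
    x = _drive(params, I_syn)
    g = params.g
    u = g * np.asarray(x, dtype=float)
    small = np.abs(u) < 1e-5
    deep = u < -500.0
    u_safe = np.where(small | deep, 1.0, u)
    with np.errstate(over="ignore"):
        e = np.exp(-u_safe)
        main = (1.0 - (1.0 + u_safe) * e) / (1.0 - e) ** 2
    series = 0.5 + u / 6.0
    out = np.where(small, series, np.where(deep, 0.0, main)) * params.gain
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Synaptic currents and the vector field
# ---------------------------------------------------------------------------

def synaptic_currents(params: ModelParams, state: State | Iterable[float],
                      stim: StimulusSample | Iterable[float]):
    """Total synaptic currents (I_syn_1, I_syn_2) in pA.

    I_syn,i = I_w_plus*S_i - I_w_minus*S_j + I_0 + I_sti,i.  With
    ``rectify_synapse`` each component is clamped at 0 from below.
    """
    s1, s2 = state
    c1, c2 = stim
    i1 = params.I_w_plus * s1 - params.I_w_minus * s2 + params.I_0 + c1
    i2 = params.I_w_plus * s2 - params.I_w_minus * s1 + params.I_0 + c2
    if params.rectify_synapse:
        i1 = np.maximum(i1, 0.0)
        i2 = np.maximum(i2, 0.0)
    return i1, i2


def firing_rates(params: ModelParams, state, stim):
    """Population firing activities (I_r1, I_r2) in pA for a state and stimulus."""
    i1, i2 = synaptic_currents(params, state, stim)
    act = rate_hard if params.activation == "hard" else rate_smooth
    return act(params, i1), act(params, i2)


def vector_field(params: ModelParams, state, stim):
    """(dS1/dt, dS2/dt) in 1/s at the given state and stimulus.

    Accepts scalar pairs or broadcastable arrays (for grid evaluation).
    """
    r1, r2 = firing_rates(params, state, stim)
    s1, s2 = state
    q = params.charge_pC
    k = params.kappa
    f1 = (-params.I_tau * np.asarray(s1, float) + (1.0 - np.asarray(s1, float)) * k * r1) / q
    f2 = (-params.I_tau * np.asarray(s2, float) + (1.0 - np.asarray(s2, float)) * k * r2) / q
    if np.ndim(f1) == 0:
        return float(f1), float(f2)
    return f1, f2


# ---------------------------------------------------------------------------
# Scalar fast path for the integrator (identical formulas, math module)
# ---------------------------------------------------------------------------

def _scalar_rate(x: float, g: float, hard: bool) -> float:
    if hard:
        return x if x > 0.0 else 0.0
    u = g * x
    if abs(u) < 1e-8:
        return (1.0 / g) * (1.0 + u / 2.0 + u * u / 12.0)
    if u < -500.0:
        return -x * math.exp(max(u, -745.0))
    return x / (-math.expm1(-u))


def field_scalar(params: ModelParams, s1: float, s2: float,
                 c1: float, c2: float) -> tuple[float, float]:
    """Scalar vector field (dS1/dt, dS2/dt), 1/s.  Symmetric arithmetic
    ordering so exactly symmetric inputs give bitwise symmetric outputs."""
    wp, wm, i0 = params.I_w_plus, params.I_w_minus, params.I_0
    isyn1 = wp * s1 - wm * s2 + i0 + c1
    isyn2 = wp * s2 - wm * s1 + i0 + c2
    if params.rectify_synapse:
        isyn1 = isyn1 if isyn1 > 0.0 else 0.0
        isyn2 = isyn2 if isyn2 > 0.0 else 0.0
    gain, thr, g = params.gain, params.I_thr_r, params.g
    hard = params.activation == "hard"
    r1 = _scalar_rate(gain * isyn1 - thr, g, hard)
    r2 = _scalar_rate(gain * isyn2 - thr, g, hard)
    q = params.charge_pC
    k = params.kappa
    f1 = (-params.I_tau * s1 + (1.0 - s1) * k * r1) / q
    f2 = (-params.I_tau * s2 + (1.0 - s2) * k * r2) / q
    return f1, f2


# ---------------------------------------------------------------------------
# Task stimuli
# ---------------------------------------------------------------------------

def decision_stimulus(amplitude: float, coherence: float) -> StimulusSample:
    """Random-dot decision stimulus (amplitude*(1+Coh), amplitude*(1-Coh)).

    ``coherence`` is the signed fraction of coherently moving dots in
    [-1, 1]; the two components always sum to 2*amplitude.
    """
    if abs(coherence) > 1:
        raise ValueError(f"|coherence| must be <= 1, got {coherence}")
    if amplitude < 0:
        raise ValueError(f"amplitude must be non-negative, got {amplitude}")
    return StimulusSample(amplitude * (1.0 + coherence), amplitude * (1.0 - coherence))


def hysteresis_coherence(t: float, T: float) -> float:
    """Linearly ramped feature coherence Coh = 1 - 2t/T for t in [0, T]."""
    if not 0 <= t <= T:
        raise ValueError(f"t must lie in [0, {T}], got {t}")
    return 1.0 - 2.0 * t / T
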