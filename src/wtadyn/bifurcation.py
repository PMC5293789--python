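"""One-parameter sweeps of the fixed-point structure.

Sweeps recompute the full fixed-point set per parameter value (2-D root
finding is cheap here) rather than continuing branches; fold locations
are recovered afterwards by bisection on the interval edges.  Supported
sweep parameters:

* ``I_sti_unbiased`` — equal stimulus to both populations, pA;
* ``Coh`` — feature/motion coherence with a fixed amplitude;
* ``I_w_plus`` — recurrent self-excitation strength, pA.
"""

from __future__ import annotations

from dataclasses import dataclass
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import ModelParams, StimulusSample, ZERO_STIMULUS, decision_stimulus
from .phaseplane import FixedPoint, MarginalStabilityError, find_fixed_points

__all__ = [
    "BifurcationDiagram",
    "sweep",
    "bistable_interval",
    "regime_label",
    "write_diagram",
]

SWEEP_PARAMETERS = ("I_sti_unbiased", "Coh", "I_w_plus")


@dataclass
class BifurcationDiagram:
    """Fixed-point sets indexed by a swept scalar parameter."""

    parameter: str
    values: np.ndarray
    fixed_points: list[list[FixedPoint]]
    marginal: list[bool]  # value-wise flag: classification failed (non-hyperbolic)

    # context needed to recompute points while refining interval edges
    params: ModelParams | None = None
    amplitude: float | None = None

    @property
    def n_total(self) -> np.ndarray:
        return np.array([len(fps) for fps in self.fixed_points])

    @property
    def n_stable(self) -> np.ndarray:
        return np.array([sum(fp.stable for fp in fps) for fps in self.fixed_points])


def _setting(params: ModelParams, parameter: str, value: float,
             base_stimulus: StimulusSample, amplitude: float):
    """(params, stimulus) pair implied by one sweep value."""
    if parameter == "I_sti_unbiased":
        return params, StimulusSample(value, value)
    if parameter == "Coh":
        return params, decision_stimulus(amplitude, value)
    if parameter == "I_w_plus":
        return params.replace(I_w_plus=value), base_stimulus
    raise ValueError(f"parameter must be one of {SWEEP_PARAMETERS}, got {parameter!r}")


def sweep(params: ModelParams, parameter: str, values,
          base_stimulus: StimulusSample = ZERO_STIMULUS,
          amplitude: float = 15.0) -> BifurcationDiagram:
    """Record the fixed-point set at each parameter value.

    ``amplitude`` is the stimulus amplitude used for Coh sweeps.
    Values where classification hits a non-hyperbolic point (exact fold)
    are flagged marginal, with unclassified points recorded.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 2 or np.any(np.diff(values) <= 0):
        raise ValueError("values must be sorted strictly increasing with >= 2 entries")
    all_fps: list[list[FixedPoint]] = []
    marginal: list[bool] = []
    for v in values:
        p, stim = _setting(params, parameter, float(v), base_stimulus, amplitude)
        try:
            fps = find_fixed_points(p, stim)
            flag = False
        except MarginalStabilityError:
            fps = find_fixed_points(p, stim, classify_points=False)
            flag = True
        all_fps.append(fps)
        marginal.append(flag)
    return BifurcationDiagram(parameter, values, all_fps, marginal,
                              params=params, amplitude=amplitude)


def _n_stable_at(params: ModelParams, parameter: str, value: float,
                 base_stimulus: StimulusSample, amplitude: float) -> int:
    p, stim = _setting(params, parameter, value, base_stimulus, amplitude)
    try:
        return sum(fp.stable for fp in find_fixed_points(p, stim))
    except MarginalStabilityError:
        return 0


def bistable_interval(diagram: BifurcationDiagram, refine_tol: float = 1e-3):
    """Maximal contiguous run of Coh values with >= 2 stable fixed points,
    with edges refined by bisection to ``refine_tol``.

    Returns (coh_lo, coh_hi) or None if the diagram has no bistable
    value.
    """
    if diagram.parameter != "Coh":
        raise ValueError("bistable_interval requires a Coh sweep")
    stable = diagram.n_stable
    values = diagram.values
    bist = stable >= 2
    if not bist.any():
        return None
    # Longest contiguous True run.
    runs = []
    i = 0
    while i < len(bist):
        if bist[i]:
            j = i
            while j + 1 < len(bist) and bist[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    i0, i1 = max(runs, key=lambda r: values[r[1]] - values[r[0]])
    lo, hi = values[i0], values[i1]
    if diagram.params is not None:
        p, amp = diagram.params, diagram.amplitude
        pred = lambda c: _n_stable_at(p, "Coh", c, ZERO_STIMULUS, amp) >= 2
        if i0 > 0:
            lo = _bisect_edge(pred, values[i0 - 1], values[i0], refine_tol, want_inside_right=True)
        if i1 < len(values) - 1:
            hi = _bisect_edge(pred, values[i1 + 1], values[i1], refine_tol, want_inside_right=False)
    return float(lo), float(hi)


def _bisect_edge(pred, outside, inside, tol, want_inside_right):
    """Bisect a boundary between a value where pred is False (outside)
    and one where it is True (inside)."""
    a, b = (outside, inside) if want_inside_right else (inside, outside)
    # invariant: pred differs between a and b
    for _ in range(60):
        if abs(b - a) < tol:
            break
        m = (a + b) / 2.0
        if pred(m) == want_inside_right:
            # m behaves like the right side
            b = m
        else:
            a = m
    return (a + b) / 2.0


def regime_label(counts: tuple[int, int]) -> str:
    """Coarse dynamical regime from (n_total, n_stable):

    (1,1) -> single_attractor; two stable states with an unstable
    symmetric point -> wta_competition; >= 3 stable -> multistable
    (spontaneous state coexists with memory states); anything else ->
    other.
    """
    n_total, n_stable = counts
    if (n_total, n_stable) == (1, 1):
        return "single_attractor"
    if n_stable == 2 and n_total >= 3:
        return "wta_competition"
    if n_stable >= 3:
        return "multistable_with_symmetric"
    return "other"


def write_diagram(diagram: BifurcationDiagram, csv_path: str | Path,
                  summary_path: str | Path | None = None,
                  interval=None) -> None:
    """CSV with columns param,value,S1,S2,class plus a JSON summary of
    per-value counts (and interval edges when supplied)."""
    rows = []
    for v, fps in zip(diagram.values, diagram.fixed_points):
        for fp in fps:
            rows.append({"param": diagram.parameter, "value": v,
                         "S1": fp.state.S1, "S2": fp.state.S2,
                         "class": fp.classification})
    pd.DataFrame(rows, columns=["param", "value", "S1", "S2", "class"]).to_csv(
        csv_path, index=False)
    if summary_path is not None:
        summary = {
            "parameter": diagram.parameter,
            "values": diagram.values.tolist(),
            "n_total": diagram.n_total.tolist(),
            "n_stable": diagram.n_stable.tolist(),
            "marginal": diagram.marginal,
            "bistable_interval": list(interval) if interval else None,
        }
        Path(summary_path).write_text(json.dumps(summary, indent=2) + "\n")
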