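"""Phase-plane analysis: nullclines, fixed points, stability.

Fixed points of the two-variable WTA field are found by a multi-start
damped-Newton iteration using the analytic Jacobian, and independently
by a brute-force sign-change grid scan (`grid_scan_fixed_points`) that
serves as an oracle for completeness.  Stability is classified from
the eigenvalues of the analytic Jacobian.

The search domain is the unit square [0,1]^2: any steady state of the
gating equations with a positive activation necessarily satisfies
S in [0,1), and the square is forward invariant.
"""

from __future__ import annotations

from dataclasses import dataclass
import json
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .model import (
    ModelParams,
    State,
    StimulusSample,
    rate_smooth,
    rate_smooth_derivative,
    synaptic_currents,
    vector_field,
)

__all__ = [
    "FixedPoint",
    "NullclineSet",
    "MarginalStabilityError",
    "nullclines",
    "find_fixed_points",
    "grid_scan_fixed_points",
    "jacobian",
    "classify",
    "saddle_time_constant",
    "write_fixed_point_table",
]

RESIDUAL_TOL = 1e-9      # 1/s, max |dS/dt| accepted at a fixed point
DEDUP_TOL = 1e-4         # max-norm separation below which roots merge
SEED_GRID = 25           # Newton seeds per axis
MARGINAL_RE = 1e-12      # 1/s, |Re lambda| below which a point is non-hyperbolic


class MarginalStabilityError(RuntimeError):
    """Raised when an eigenvalue real part is numerically zero
    (non-hyperbolic fixed point)."""


@dataclass(frozen=True)
class FixedPoint:
    """A root of the vector field with its linearisation.

    ``time_constants`` are 1/|Re lambda| per eigenvalue in seconds;
    ``residual`` is max |dS/dt| at the root in 1/s.
    """

    state: State
    eigenvalues: tuple[complex, complex]
    classification: str  # stable_node/stable_focus/saddle/unstable_node/unstable_focus
    time_constants: tuple[float, float]
    residual: float

    @property
    def stable(self) -> bool:
        return self.classification.startswith("stable")

    @property
    def is_saddle(self) -> bool:
        return self.classification == "saddle"

    def to_dict(self) -> dict:
        l1, l2 = self.eigenvalues
        return {
            "S1": self.state.S1, "S2": self.state.S2,
            "class": self.classification,
            "re_lambda1": l1.real, "re_lambda2": l2.real,
            "tau1_s": self.time_constants[0], "tau2_s": self.time_constants[1],
        }


@dataclass(frozen=True)
class NullclineSet:
    """Vertex sets of the two nullclines dS1/dt = 0 and dS2/dt = 0,
    each an (N, 2) array of (S1, S2) points in the unit square."""

    curve1: np.ndarray
    curve2: np.ndarray


# ---------------------------------------------------------------------------
# Jacobian
# ---------------------------------------------------------------------------

def jacobian(params: ModelParams, state, stim) -> np.ndarray:
    """Analytic 2x2 Jacobian of the vector field at ``state`` (units 1/s
    per unit S).  Requires the smooth activation; the hard rectifier is
    not differentiable at threshold."""
    if params.activation != "smooth":
        raise NotImplementedError("jacobian requires the smooth activation")
    s1, s2 = state
    i1, i2 = synaptic_currents(params, state, stim)
    r1 = rate_smooth(params, i1)
    r2 = rate_smooth(params, i2)
    rp1 = rate_smooth_derivative(params, i1)
    rp2 = rate_smooth_derivative(params, i2)
    if params.rectify_synapse:
        # Clamped branch has zero sensitivity to the state.
        raw1 = params.I_w_plus * s1 - params.I_w_minus * s2 + params.I_0 + stim[0]
        raw2 = params.I_w_plus * s2 - params.I_w_minus * s1 + params.I_0 + stim[1]
        rp1 = rp1 * (raw1 > 0.0)
        rp2 = rp2 * (raw2 > 0.0)
    k = params.kappa
    q = params.charge_pC
    wp, wm = params.I_w_plus, params.I_w_minus
    j11 = (-params.I_tau - k * r1 + (1.0 - s1) * k * rp1 * wp) / q
    j12 = ((1.0 - s1) * k * rp1 * (-wm)) / q
    j21 = ((1.0 - s2) * k * rp2 * (-wm)) / q
    j22 = (-params.I_tau - k * r2 + (1.0 - s2) * k * rp2 * wp) / q
    return np.array([[j11, j12], [j21, j22]], dtype=float)


# ---------------------------------------------------------------------------
# Batched damped Newton
# ---------------------------------------------------------------------------

def _field_batch(params: ModelParams, S: np.ndarray, stim) -> np.ndarray:
    f1, f2 = vector_field(params, (S[:, 0], S[:, 1]), stim)
    return np.column_stack([f1, f2])


def _jac_batch(params: ModelParams, S: np.ndarray, stim) -> np.ndarray:
    s1, s2 = S[:, 0], S[:, 1]
    i1, i2 = synaptic_currents(params, (s1, s2), stim)
    r1 = rate_smooth(params, i1)
    r2 = rate_smooth(params, i2)
    rp1 = rate_smooth_derivative(params, i1)
    rp2 = rate_smooth_derivative(params, i2)
    k, q = params.kappa, params.charge_pC
    wp, wm = params.I_w_plus, params.I_w_minus
    J = np.empty((len(S), 2, 2))
    J[:, 0, 0] = (-params.I_tau - k * r1 + (1.0 - s1) * k * rp1 * wp) / q
    J[:, 0, 1] = ((1.0 - s1) * k * rp1 * (-wm)) / q
    J[:, 1, 0] = ((1.0 - s2) * k * rp2 * (-wm)) / q
    J[:, 1, 1] = (-params.I_tau - k * r2 + (1.0 - s2) * k * rp2 * wp) / q
    return J


def _newton_polish(params: ModelParams, seeds: np.ndarray, stim,
                   max_iter: int = 80, max_halvings: int = 30) -> np.ndarray:
    """Damped Newton from a batch of seeds; returns converged roots
    (possibly duplicated).  Diverging seeds are silently dropped."""
    S = seeds.copy()
    converged: list[np.ndarray] = []
    tol = RESIDUAL_TOL * 1e-3
    for _ in range(max_iter):
        if len(S) == 0:
            break
        F = _field_batch(params, S, stim)
        res = np.abs(F).max(axis=1)
        done = res < tol
        if done.any():
            converged.append(S[done])
            S, F, res = S[~done], F[~done], res[~done]
            if len(S) == 0:
                break
        J = _jac_batch(params, S, stim)
        det = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
        singular = np.abs(det) < 1e-300
        det = np.where(singular, 1.0, det)
        d0 = (J[:, 1, 1] * F[:, 0] - J[:, 0, 1] * F[:, 1]) / det
        d1 = (-J[:, 1, 0] * F[:, 0] + J[:, 0, 0] * F[:, 1]) / det
        step = np.column_stack([d0, d1])
        keep = ~singular
        S, F, res, step = S[keep], F[keep], res[keep], step[keep]
        # Backtracking: halve the step until the residual does not grow.
        alpha = np.ones(len(S))
        newS = S - step
        for _h in range(max_halvings):
            newres = np.abs(_field_batch(params, newS, stim)).max(axis=1)
            worse = newres > res
            if not worse.any():
                break
            alpha = np.where(worse, alpha / 2.0, alpha)
            newS = S - alpha[:, None] * step
        S = newS
        # Drop runaways; collapse seeds that have merged onto one basin.
        S = S[(np.abs(S - 0.5) <= 2.0).all(axis=1)]
        if len(S):
            keys = np.round(S / 1e-6).astype(np.int64)
            _, uidx = np.unique(keys, axis=0, return_index=True)
            S = S[np.sort(uidx)]
    roots = np.vstack(converged) if converged else np.empty((0, 2))
    inside = ((roots[:, 0] > -1e-9) & (roots[:, 0] < 1 + 1e-9)
              & (roots[:, 1] > -1e-9) & (roots[:, 1] < 1 + 1e-9))
    return roots[inside]


def _dedup(points: np.ndarray, tol: float = DEDUP_TOL) -> list[np.ndarray]:
    out: list[np.ndarray] = []
    for p in points:
        if not any(np.max(np.abs(p - q)) < tol for q in out):
            out.append(p)
    return sorted(out, key=lambda p: (p[0], p[1]))


def find_fixed_points(params: ModelParams, stim: StimulusSample,
                      classify_points: bool = True) -> list[FixedPoint]:
    """All roots of the vector field in [0,1]^2, as classified FixedPoints.

    Multi-start damped Newton from a uniform seed grid, polished to
    residual < 1e-9 /s, deduplicated at 1e-4 max-norm and sorted
    lexicographically by (S1, S2).
    """
    ax = np.linspace(0.0, 1.0, SEED_GRID)
    g1, g2 = np.meshgrid(ax, ax, indexing="ij")
    seeds = np.column_stack([g1.ravel(), g2.ravel()])
    roots = _newton_polish(params, seeds, stim)
    points = _dedup(np.clip(roots, 0.0, 1.0))
    if not classify_points:
        return [FixedPoint(State(*p), (0j, 0j), "unclassified", (np.inf, np.inf),
                           float(np.max(np.abs(vector_field(params, p, stim)))))
                for p in points]
    return [classify(State(float(p[0]), float(p[1])), params, stim) for p in points]


def grid_scan_fixed_points(params: ModelParams, stim: StimulusSample,
                           n: int = 400) -> list[State]:
    """Independent brute-force root localisation.

    Partitions [0,1]^2 into n x n cells, flags cells where *both*
    components of the field change sign across the cell corners,
    merges adjacent flagged cells into clusters, and refines each
    cluster by recursive subdivision (bisection on the cell).  Returns
    one representative State per cluster.
    """
    if n < 200:
        raise ValueError("n must be >= 200 for a reliable scan")
    ax = np.linspace(0.0, 1.0, n + 1)
    G1, G2 = np.meshgrid(ax, ax, indexing="ij")
    f1, f2 = vector_field(params, (G1, G2), tuple(stim))

    def cell_flags(a):
        corners = np.stack([a[:-1, :-1], a[1:, :-1], a[:-1, 1:], a[1:, 1:]])
        return (corners.min(axis=0) <= 0) & (corners.max(axis=0) >= 0)

    flagged = cell_flags(f1) & cell_flags(f2)
    # Merge adjacent flagged cells (8-connectivity) into clusters.
    visited = np.zeros_like(flagged)
    clusters = []
    idxs = np.argwhere(flagged)
    flag_set = set(map(tuple, idxs))
    neighbours = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]
    for start in map(tuple, idxs):
        if visited[start]:
            continue
        stack = [start]
        comp = []
        visited[start] = True
        while stack:
            i, j = stack.pop()
            comp.append((i, j))
            for di, dj in neighbours:
                nb = (i + di, j + dj)
                if nb in flag_set and not visited[nb]:
                    visited[nb] = True
                    stack.append(nb)
        clusters.append(comp)

    h = 1.0 / n
    candidates = []
    for comp in clusters:
        i = np.array([c[0] for c in comp])
        j = np.array([c[1] for c in comp])
        lo = np.array([i.min() * h, j.min() * h])
        hi = np.array([(i.max() + 1) * h, (j.max() + 1) * h])
        point = _refine_box(params, stim, lo, hi)
        if point is not None:
            candidates.append(point)
    # Nearby nullcline tangencies can flag several clusters around one
    # root; merge representatives well below the >1e-2 root separation.
    merged: list[np.ndarray] = []
    for p in sorted(candidates, key=lambda p: (p[0], p[1])):
        if not any(np.max(np.abs(p - q)) < 5e-3 for q in merged):
            merged.append(p)
    return [State(float(p[0]), float(p[1])) for p in merged]


def _refine_box(params: ModelParams, stim, lo, hi, max_nodes: int = 400):
    """Bisection refinement with backtracking.

    Depth-first subdivision of the box, descending into subboxes whose
    sampled corners/center still show a sign change in *both* field
    components; a 3x3 sample grid per subbox keeps interior sign
    structure visible.  Returns the midpoint of the first subbox shrunk
    below 1e-8, or None when every branch loses the sign change
    (flagged cells without a root)."""

    def has_root_signs(a0, a1, b0, b1):
        xs = np.linspace(a0, a1, 3)
        ys = np.linspace(b0, b1, 3)
        X, Y = np.meshgrid(xs, ys, indexing="ij")
        f1, f2 = vector_field(params, (X, Y), tuple(stim))
        return f1.min() <= 0 <= f1.max() and f2.min() <= 0 <= f2.max()

    stack = [(np.asarray(lo, float), np.asarray(hi, float))]
    nodes = 0
    while stack and nodes < max_nodes:
        lo, hi = stack.pop()
        nodes += 1
        if max(hi - lo) < 1e-8:
            return (lo + hi) / 2.0
        mid = (lo + hi) / 2.0
        for a0, a1 in ((lo[0], mid[0]), (mid[0], hi[0])):
            for b0, b1 in ((lo[1], mid[1]), (mid[1], hi[1])):
                if has_root_signs(a0, a1, b0, b1):
                    stack.append((np.array([a0, b0]), np.array([a1, b1])))
    return None


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify(fp_state: State, params: ModelParams, stim: StimulusSample) -> FixedPoint:
    """Eigen-classify a (pre-polished) fixed point.

    Raises MarginalStabilityError if either eigenvalue's real part is
    numerically zero (non-hyperbolic).
    """
    f = vector_field(params, tuple(fp_state), tuple(stim))
    residual = float(max(abs(f[0]), abs(f[1])))
    if residual > RESIDUAL_TOL:
        raise ValueError(f"state is not a fixed point (residual {residual:.3e} /s)")
    J = jacobian(params, tuple(fp_state), tuple(stim))
    lams = np.linalg.eigvals(J)
    re = np.real(lams)
    if np.any(np.abs(re) < MARGINAL_RE):
        raise MarginalStabilityError(
            f"non-hyperbolic fixed point at ({fp_state.S1:.6f}, {fp_state.S2:.6f})")
    complex_pair = abs(np.imag(lams[0])) > 1e-12
    if re[0] < 0 and re[1] < 0:
        cls = "stable_focus" if complex_pair else "stable_node"
    elif re[0] > 0 and re[1] > 0:
        cls = "unstable_focus" if complex_pair else "unstable_node"
    else:
        cls = "saddle"
    taus = tuple(1.0 / abs(r) for r in re)
    return FixedPoint(fp_state, (complex(lams[0]), complex(lams[1])), cls, taus, residual)


# ---------------------------------------------------------------------------
# Nullclines
# ---------------------------------------------------------------------------

def nullclines(params: ModelParams, stim: StimulusSample,
               resolution: int = 200) -> NullclineSet:
    """Zero contours of dS1/dt and dS2/dt over [0,1]^2.

    Sign changes are located on the edges of a resolution x resolution
    grid and refined by bisection along each edge to |dS_i/dt| < 1e-8 /s.
    """
    if resolution < 50:
        raise ValueError("resolution must be >= 50")
    ax = np.linspace(0.0, 1.0, resolution + 1)
    G1, G2 = np.meshgrid(ax, ax, indexing="ij")
    fields = vector_field(params, (G1, G2), tuple(stim))
    curves = []
    for comp, f in enumerate(fields):
        pts = []
        # Vertical edges (vary S1 at fixed S2) and horizontal edges.
        for (A, B, fixed_axis) in (
            (f[:-1, :], f[1:, :], 1),   # step in S1
            (f[:, :-1], f[:, 1:], 0),   # step in S2
        ):
            ii, jj = np.where((A <= 0) != (B <= 0))
            for i, j in zip(ii, jj):
                if fixed_axis == 1:
                    p0 = np.array([ax[i], ax[j]])
                    p1 = np.array([ax[i + 1], ax[j]])
                else:
                    p0 = np.array([ax[i], ax[j]])
                    p1 = np.array([ax[i], ax[j + 1]])
                pts.append(_bisect_edge(params, stim, comp, p0, p1))
        pts = np.array(sorted(pts, key=lambda p: (p[1], p[0]))) if pts else np.empty((0, 2))
        curves.append(pts)
    return NullclineSet(curves[0], curves[1])


def _bisect_edge(params, stim, comp, p0, p1, tol: float = 1e-8) -> np.ndarray:
    f0 = vector_field(params, tuple(p0), tuple(stim))[comp]
    for _ in range(80):
        mid = (p0 + p1) / 2.0
        fm = vector_field(params, tuple(mid), tuple(stim))[comp]
        if abs(fm) < tol:
            return mid
        if (f0 <= 0) == (fm <= 0):
            p0, f0 = mid, fm
        else:
            p1 = mid
    return (p0 + p1) / 2.0


# ---------------------------------------------------------------------------
# Saddle time constant
# ---------------------------------------------------------------------------

def saddle_time_constant(params: ModelParams, stim: StimulusSample):
    """Unstable-manifold time constant of the symmetric fixed point.

    Locates the fixed point on the diagonal S1 = S2 (the stimulus must
    be unbiased for one to exist), and returns 1/Re(lambda+) for its
    positive eigenvalue if it is a saddle; None if the symmetric point
    is not a saddle.
    """
    if abs(stim.I_sti_1 - stim.I_sti_2) > 1e-12:
        raise ValueError("symmetric fixed point requires an unbiased stimulus")

    def fdiag(s):
        return vector_field(params, (s, s), tuple(stim))[0]

    ss = np.linspace(0.0, 1.0, 801)
    vals = np.array([fdiag(s) for s in ss])
    roots = []
    for i in range(len(ss) - 1):
        if vals[i] == 0.0:
            roots.append(ss[i])
        elif vals[i] * vals[i + 1] < 0:
            roots.append(brentq(fdiag, ss[i], ss[i + 1], xtol=1e-14))
    if not roots:
        raise RuntimeError("no symmetric fixed point found on the diagonal")
    # With multiple diagonal roots, the saddle (if any) is the one with a
    # positive transverse eigenvalue; check each.
    for r in roots:
        fp = classify(State(float(r), float(r)), params, stim)
        if fp.is_saddle:
            lam_plus = max(l.real for l in fp.eigenvalues)
            return 1.0 / lam_plus
    return None


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def write_fixed_point_table(fps: list[FixedPoint], path: str | Path) -> None:
    """JSON list of {S1, S2, class, re_lambda1, re_lambda2, tau1_s, tau2_s}."""
    Path(path).write_text(json.dumps([fp.to_dict() for fp in fps], indent=2) + "\n")
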