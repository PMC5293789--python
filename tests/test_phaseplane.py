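"""Phase-plane tests: nullclines, fixed-point structure of the printed
configurations, Newton-vs-grid oracle equivalence, Jacobian accuracy,
stability classification and saddle time constants."""

import numpy as np
import pytest
from scipy.optimize import brentq

from wtadyn import (
    ModelParams,
    State,
    StimulusSample,
    ZERO_STIMULUS,
    classify,
    find_fixed_points,
    grid_scan_fixed_points,
    jacobian,
    nullclines,
    saddle_time_constant,
    settle_to_attractor,
    vector_field,
    write_fixed_point_table,
)
from wtadyn.phaseplane import MarginalStabilityError

from conftest import WTA_AMPLITUDE

# (I_w_plus, expected total, expected stable) at zero stimulus — the
# three printed attractor structures: single spontaneous state, the
# 5-point working-memory structure, the 9-point structure with the
# two-item memory attractor.
PRINTED_STRUCTURES = [(100.0, 1, 1), (200.0, 5, 3), (250.0, 9, 4)]


@pytest.fixture(scope="module")
def printed_fps():
    out = {}
    for wp, _, _ in PRINTED_STRUCTURES:
        p = ModelParams(I_w_plus=wp, I_w_minus=60.0)
        out[wp] = (p, find_fixed_points(p, ZERO_STIMULUS))
    return out


class TestFixedPointStructure:
    @pytest.mark.parametrize("wp,n_total,n_stable", PRINTED_STRUCTURES)
    def test_printed_counts(self, printed_fps, wp, n_total, n_stable):
        _, fps = printed_fps[wp]
        assert len(fps) == n_total
        assert sum(fp.stable for fp in fps) == n_stable

    @pytest.mark.parametrize("wp,n_total,n_stable", PRINTED_STRUCTURES)
    def test_grid_oracle_equivalence(self, printed_fps, wp, n_total, n_stable):
        """The brute-force sign-change scan finds the same roots as the
        Newton search, one-to-one within 1e-3, at every resolution."""
        p, fps = printed_fps[wp]
        locs = [(fp.state.S1, fp.state.S2) for fp in fps]
        for n in (200, 400):
            scan = grid_scan_fixed_points(p, ZERO_STIMULUS, n)
            assert len(scan) == len(fps)
            for s in scan:
                assert min(max(abs(s.S1 - a), abs(s.S2 - b)) for a, b in locs) < 1e-3

    def test_grid_scan_validates_resolution(self, decision_params):
        with pytest.raises(ValueError):
            grid_scan_fixed_points(decision_params, ZERO_STIMULUS, 100)

    def test_residuals_below_tolerance(self, printed_fps):
        for _, (p, fps) in printed_fps.items():
            for fp in fps:
                assert fp.residual < 1e-9

    def test_sorted_lexicographically(self, printed_fps):
        for _, (_, fps) in printed_fps.items():
            keys = [(fp.state.S1, fp.state.S2) for fp in fps]
            assert keys == sorted(keys)

    def test_globally_contracting_when_uncoupled(self):
        p = ModelParams(I_w_plus=1e-9, I_w_minus=1e-9)
        fps = find_fixed_points(p, ZERO_STIMULUS)
        assert len(fps) == 1 and fps[0].stable
        assert len(grid_scan_fixed_points(p, ZERO_STIMULUS, 200)) == 1

    def test_symmetric_stimulus_set_is_exchange_invariant(self, printed_fps):
        for _, (_, fps) in printed_fps.items():
            locs = {(round(fp.state.S1, 6), round(fp.state.S2, 6)) for fp in fps}
            assert {(b, a) for a, b in locs} == locs

    def test_poincare_index_consistency(self, printed_fps):
        """On the trapping square, #stable + #unstable nodes/foci minus
        #saddles is 1 for every hyperbolic configuration."""
        for _, (_, fps) in printed_fps.items():
            stable = sum(fp.stable for fp in fps)
            unstable = sum(fp.classification.startswith("unstable") for fp in fps)
            saddles = sum(fp.is_saddle for fp in fps)
            assert stable + unstable - saddles == 1

    def test_stable_points_are_attracting(self, printed_fps):
        for _, (p, fps) in printed_fps.items():
            for fp in fps:
                if not fp.stable:
                    continue
                start = State(min(fp.state.S1 + 1e-3, 1.0), max(fp.state.S2 - 1e-3, 0.0))
                res = settle_to_attractor(p, ZERO_STIMULUS, start)
                assert res.settled
                assert abs(res.state.S1 - fp.state.S1) < 1e-4
                assert abs(res.state.S2 - fp.state.S2) < 1e-4

    def test_memory_saddles_flank_the_memory_attractors(self, wm_params_200):
        """In the 5-point structure the two off-diagonal unstable points
        separating spontaneous from memory states are saddles."""
        fps = find_fixed_points(wm_params_200, ZERO_STIMULUS)
        unstable = [fp for fp in fps if not fp.stable]
        assert len(unstable) == 2
        assert all(fp.is_saddle for fp in unstable)

    def test_table_writer(self, tmp_path, printed_fps):
        import json
        _, fps = printed_fps[200.0]
        path = tmp_path / "fps.json"
        write_fixed_point_table(fps, path)
        rows = json.loads(path.read_text())
        assert len(rows) == 5
        assert set(rows[0]) == {"S1", "S2", "class", "re_lambda1", "re_lambda2", "tau1_s", "tau2_s"}


class TestJacobian:
    def test_matches_finite_differences(self, decision_params):
        rng = np.random.default_rng(7)
        stim = (12.0, 20.0)
        h = 1e-6
        for _ in range(100):
            s = rng.uniform(0.0, 1.0, 2)
            J = jacobian(decision_params, s, stim)
            J_fd = np.empty((2, 2))
            for j in range(2):
                e = np.zeros(2)
                e[j] = h
                fp = vector_field(decision_params, s + e, stim)
                fm = vector_field(decision_params, s - e, stim)
                J_fd[:, j] = (np.array(fp) - np.array(fm)) / (2 * h)
            assert np.max(np.abs(J - J_fd)) / np.max(np.abs(J)) < 1e-6

    def test_off_diagonal_sign_structure(self, decision_params):
        """Mutual inhibition makes each population's growth decrease in
        the other's gating variable."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            s = rng.uniform(0.0, 1.0, 2)
            J = jacobian(decision_params, s, (15.0, 15.0))
            assert J[0, 1] <= 0 and J[1, 0] <= 0

    def test_spontaneous_state_is_linearly_stable(self, decision_params):
        fp = find_fixed_points(decision_params, ZERO_STIMULUS)[0]
        assert all(l.real < 0 for l in fp.eigenvalues)

    def test_hard_activation_unsupported(self):
        p = ModelParams(I_w_plus=100.0, I_w_minus=60.0, activation="hard")
        with pytest.raises(NotImplementedError):
            jacobian(p, (0.1, 0.1), (0.0, 0.0))


class TestClassify:
    def test_definitions(self, wm_params_200):
        fps = find_fixed_points(wm_params_200, ZERO_STIMULUS)
        for fp in fps:
            re = [l.real for l in fp.eigenvalues]
            if fp.stable:
                assert all(r < 0 for r in re)
            elif fp.is_saddle:
                assert re[0] * re[1] < 0
            else:
                assert all(r > 0 for r in re)
            assert fp.time_constants == pytest.approx(
                tuple(1.0 / abs(r) for r in re))

    def test_rejects_non_fixed_point(self, decision_params):
        with pytest.raises(ValueError):
            classify(State(0.5, 0.5), decision_params, ZERO_STIMULUS)


class TestNullclines:
    def test_vertices_satisfy_own_equation(self, decision_params):
        ncs = nullclines(decision_params, ZERO_STIMULUS, resolution=100)
        for comp, curve in ((0, ncs.curve1), (1, ncs.curve2)):
            assert len(curve) > 50
            for p in curve[::7]:
                f = vector_field(decision_params, tuple(p), (0.0, 0.0))
                assert abs(f[comp]) < 1e-8

    def test_resolution_validation(self, decision_params):
        with pytest.raises(ValueError):
            nullclines(decision_params, ZERO_STIMULUS, resolution=10)

    def test_single_intersection_in_decision_config(self, decision_params):
        """Without stimulus the two nullclines of the decision
        configuration intersect exactly once (the spontaneous state),
        and that intersection lies on both computed curves."""
        fps = find_fixed_points(decision_params, ZERO_STIMULUS)
        assert len(fps) == 1
        ncs = nullclines(decision_params, ZERO_STIMULUS, resolution=200)
        s = fps[0].state.as_array()
        for curve in (ncs.curve1, ncs.curve2):
            assert np.min(np.max(np.abs(curve - s), axis=1)) < 2e-2

    def test_without_inhibition_s1_nullcline_ignores_s2(self):
        """With vanishing mutual inhibition the dS1/dt=0 locus is a set
        of vertical lines: its S1 roots do not depend on S2."""
        p = ModelParams(I_w_plus=100.0, I_w_minus=1e-12)
        stim = (10.0, 10.0)

        def s1_roots(s2):
            f = lambda s1: vector_field(p, (s1, s2), stim)[0]
            grid = np.linspace(0.0, 1.0, 200)
            vals = [f(s) for s in grid]
            return [brentq(f, grid[i], grid[i + 1])
                    for i in range(len(grid) - 1) if vals[i] * vals[i + 1] < 0]

        roots = [s1_roots(s2) for s2 in (0.1, 0.5, 0.9)]
        assert all(len(r) == len(roots[0]) for r in roots)
        for r in roots[1:]:
            assert np.allclose(r, roots[0], atol=1e-8)


class TestSaddleTimeConstant:
    def test_none_when_symmetric_state_is_stable(self, decision_params):
        assert saddle_time_constant(decision_params, ZERO_STIMULUS) is None

    def test_requires_unbiased_stimulus(self, decision_params):
        with pytest.raises(ValueError):
            saddle_time_constant(decision_params, StimulusSample(10.0, 20.0))

    def test_matches_trajectory_divergence_fit(self, decision_params):
        """1/Re(lambda+) from the eigen-decomposition agrees with the
        e-folding time fitted from two trajectories straddling the
        diagonal near the saddle."""
        from wtadyn import StimulusProtocol, integrate
        stim = StimulusSample(WTA_AMPLITUDE, WTA_AMPLITUDE)
        tau = saddle_time_constant(decision_params, stim)
        assert tau is not None and tau > 0
        # locate the diagonal saddle
        fps = find_fixed_points(decision_params, stim)
        saddle = next(fp for fp in fps if fp.is_saddle and abs(fp.state.S1 - fp.state.S2) < 1e-9)
        eps = 1e-7
        protocol = StimulusProtocol.constant(stim, 1.5)
        traj = integrate(decision_params, protocol,
                         State(saddle.state.S1 + eps, saddle.state.S2 - eps), dt=1e-4)
        d = traj.S1 - traj.S2
        mask = (d > 1e-6) & (d < 1e-3)  # linear-growth window
        slope = np.polyfit(traj.times[mask], np.log(d[mask]), 1)[0]
        assert 1.0 / slope == pytest.approx(tau, rel=0.05)

    def test_u_shape_along_stimulus_sweep(self, decision_params):
        """Across the competition regime the unstable-manifold time
        constant of the symmetric saddle first shrinks then grows with
        the unbiased stimulus strength."""
        strengths = [30.0, 35.0, 40.0, 45.0, 50.0]
        taus = [saddle_time_constant(decision_params, StimulusSample(a, a))
                for a in strengths]
        assert all(t is not None for t in taus)
        k_min = int(np.argmin(taus))
        assert 0 < k_min < len(taus) - 1
        assert all(taus[i] > taus[i + 1] for i in range(k_min))
        assert all(taus[i] < taus[i + 1] for i in range(k_min, len(taus) - 1))
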