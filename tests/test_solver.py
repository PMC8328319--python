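"""Solver oracles: transmission-line, Windkessel and DC-balance physics.

Each test checks the coupled 1D scheme against an independent analytic
prediction: Poiseuille/Ohmic pressure drop, matched-termination
reflectionlessness, closed-end reflection, Windkessel limits, and
volume conservation at the periodic steady state.
"""

import numpy as np
import pytest

from cvwaves.arterial import (
    MMHG,
    RHO,
    ArterialTree,
    ArterySegment,
    TerminalWindkessel,
    tree_aggregates,
)
from cvwaves.heart import LVParameters
from cvwaves.solver import (
    CFLError,
    SolverConfig,
    ValveState,
    build_state,
    junction_solve,
    run_simulation,
    step_tree,
    terminal_update,
    valve_flow,
)

HEART = LVParameters(Ees=3.0, Vd=-2.0, EDV=97.0)


def _tube_tree(L=60.0, r=1.0, cp=0.005, n=61, R1=None, R2=0.0, C=1e-6,
               P_out=0.0, sites=None):
    seg = ArterySegment(id="tube", name="tube", length=L, proximal_radius=r,
                        distal_radius=r, area_compliance=cp, n_grid_nodes=n)
    if R1 is None:
        R1 = seg.char_impedance(L)
    wk = TerminalWindkessel(R1=R1, R2=R2, C=C, P_out=P_out)
    sites = sites or {"aortic_root": ("tube", 0.0), "mid": ("tube", L / 2),
                      "end": ("tube", L)}
    return ArterialTree(segments={"tube": seg}, topology={},
                        terminals={"tube": wk}, sites=sites)


def _launch_forward_pulse(state, x0=15.0, width=3.0, amp=8.0):
    """Superpose a rightward-travelling pressure pulse on a quiescent tube."""
    n = state.seg_n[0]
    dx = state.seg_dx[0]
    x = np.arange(n) * dx
    dp_cgs = amp * MMHG * np.exp(-0.5 * ((x - x0) / width) ** 2)
    c0 = np.sqrt(state.A / (RHO * state.Cp))
    state.A = state.A + dp_cgs * state.Cp
    state.Q = state.A * dp_cgs / (RHO * c0)
    a, b = 0, n - 1
    state.seg_vol[0] = (0.5 * (state.A[a] + state.A[b])
                        + state.A[a + 1:b].sum()) * dx


def _quiet_heart():
    """LV too weak to open the valve against an 80 mmHg tube."""
    return LVParameters(Ees=0.1, Vd=0.0, EDV=10.0)


class TestPulsePropagation:
    def test_matched_termination_is_reflectionless(self):
        # R1 = tube characteristic impedance, R2 = 0, load referenced to
        # the resting pressure so the quiescent tube is in equilibrium
        tree = _tube_tree(n=241, P_out=80.0)
        cfg = SolverConfig(P_init=80.0)
        state = build_state(tree, _quiet_heart(), cfg)
        _launch_forward_pulse(state, width=6.0, amp=8.0)
        seg = tree.segments["tube"]
        c = seg.wave_speed()
        n_steps = int(1.4 * seg.length / c / state.dt)
        recP, recQ, _ = step_tree(state, n_steps)
        i_mid = state.rec_names.index("mid")
        zc = seg.char_impedance()
        pb = 0.5 * ((recP[:, i_mid] - 80.0) - zc * recQ[:, i_mid])
        pf = 0.5 * ((recP[:, i_mid] - 80.0) + zc * recQ[:, i_mid])
        assert np.ptp(pb) < 0.03 * np.ptp(pf)

    def test_closed_end_reflects_with_unit_coefficient(self):
        tree = _tube_tree(n=241, R1=1e7, C=1e-8)  # effectively sealed
        cfg = SolverConfig(P_init=80.0)
        state = build_state(tree, _quiet_heart(), cfg)
        amp = 8.0
        _launch_forward_pulse(state, width=6.0, amp=amp)
        seg = tree.segments["tube"]
        c = seg.wave_speed()
        # run until just after the pulse reaches the far end
        n_steps = int(((60.0 - 15.0) / c + 0.02) / state.dt)
        recP, _, _ = step_tree(state, n_steps)
        i_end = state.rec_names.index("end")
        peak = np.max(recP[:, i_end]) - 80.0
        gamma = peak / amp - 1.0
        assert gamma == pytest.approx(1.0, abs=0.10)

    def test_steady_viscous_pressure_drop(self):
        # narrow tube: the friction-law resistance dominates; the mean
        # inlet-outlet drop must match Q * R_viscous (Ohmic oracle)
        tree = _tube_tree(L=20.0, r=0.3, cp=5.6e-4, n=21, R1=2.2, R2=2.0,
                          C=0.2, sites={"aortic_root": ("tube", 0.0),
                                        "end": ("tube", 20.0)})
        heart = LVParameters(Ees=5.0, Vd=0.0, EDV=40.0)
        res = run_simulation(heart, tree, SolverConfig(max_cycles=40,
                                                       conv_tol=1e-3))
        assert res.converged
        wk = tree.terminals["tube"]
        r_total = (tree.segments["tube"].poiseuille_resistance()
                   + wk.R1 + wk.R2)
        co_mls = res.SV * heart.HR / 60.0
        dp = res.pressure("aortic_root").mean() - wk.P_out
        assert dp == pytest.approx(co_mls * r_total, rel=0.02)


class TestWindkessel:
    WK = TerminalWindkessel(R1=0.04, R2=1.18, C=0.26, P_out=5.0)

    def test_dc_limit(self):
        q, dt = 70.0, 1e-3
        p_stored = 5.0
        for _ in range(20000):
            p_term, p_stored = terminal_update(self.WK, p_stored, q, dt)
        assert p_term == pytest.approx(5.0 + q * (0.04 + 1.18), rel=1e-3)

    def test_rc_decay_constant(self):
        dt = 1e-4
        tau = self.WK.R2 * self.WK.C
        p_stored = 100.0
        n = int(tau / dt)
        for _ in range(n):
            _, p_stored = terminal_update(self.WK, p_stored, 0.0, dt)
        expected = 5.0 + (100.0 - 5.0) * np.exp(-1.0)
        assert p_stored == pytest.approx(expected, rel=0.01)

    def test_high_frequency_impedance_approaches_r1(self):
        # at 400 Hz the capacitor shunt (1/(w C) ~ 0.0015) is negligible
        # against R1 = 0.04
        f, dt = 400.0, 2e-6
        t = np.arange(int(0.05 / dt)) * dt
        q = 50.0 * np.sin(2 * np.pi * f * t)
        p_stored, out = 5.0, []
        for qi in q:
            p_term, p_stored = terminal_update(self.WK, p_stored, qi, dt)
            out.append(p_term)
        out = np.array(out[len(out) // 2:])
        amp_ratio = 0.5 * np.ptp(out) / 50.0
        assert amp_ratio == pytest.approx(self.WK.R1, rel=0.05)


class TestValve:
    def test_closed_diode(self):
        s = valve_flow(60.0, 80.0, ValveState(), dt=1e-4)
        assert s.Q_valve == 0.0
        assert s.open_fraction == 0.0

    def test_steady_open_flow_is_bernoulli_limited(self):
        B = SolverConfig.valve_B
        s = ValveState()
        for _ in range(30000):
            s = valve_flow(90.0, 80.0, s, dt=1e-4, B=B)
        assert s.open_fraction == pytest.approx(1.0, abs=1e-6)
        assert s.Q_valve == pytest.approx(np.sqrt(10.0 / B), rel=1e-3)

    def test_no_regurgitation_state(self):
        with pytest.raises(ValueError):
            ValveState(open_fraction=1.0, Q_valve=-1.0)


class TestJunction:
    CP = 0.01 / MMHG  # CGS area compliance per cm

    def _w1(self, A, u, cp):
        return u + 2.0 * np.sqrt(A / (RHO * cp))

    def _w2(self, A, u, cp):
        return u - 2.0 * np.sqrt(A / (RHO * cp))

    def test_symmetric_split(self):
        A_p, u_p = 3.0, 15.0
        child = (1.5, 0.0, self._w2(1.5, 0.0, self.CP), 1.5, self.CP)
        (A_pn, u_pn), kids = junction_solve(
            (A_p, u_p, self._w1(A_p, u_p, self.CP), A_p, self.CP),
            [child, child],
        )
        (A1, u1), (A2, u2) = kids
        assert A1 == pytest.approx(A2, rel=1e-12)
        assert u1 == pytest.approx(u2, rel=1e-12)
        # exact mass conservation
        assert A_pn * u_pn == pytest.approx(A1 * u1 + A2 * u2, rel=1e-9)

    def test_total_pressure_continuity(self):
        parent = (3.0, 20.0, self._w1(3.0, 20.0, self.CP), 3.0, self.CP)
        child = (2.0, 5.0, self._w2(2.0, 5.0, self.CP / 2), 2.0, self.CP / 2)
        (A_p, u_p), [(A_c, u_c)] = junction_solve(parent, [child])
        tp_p = (A_p - 3.0) / self.CP + 0.5 * RHO * u_p ** 2
        tp_c = (A_c - 2.0) / (self.CP / 2) + 0.5 * RHO * u_c ** 2
        assert tp_p == pytest.approx(tp_c, abs=1e-4 * abs(tp_p) + 1e-6)

    def test_transparent_junction_matches_single_tube(self):
        # a segment split in two with identical properties must behave
        # as the unsplit tube
        single = _tube_tree(L=60.0, r=1.0, cp=0.005, n=61, R2=1.0, C=0.5)
        half = ArterySegment(id="a", name="a", length=30.0, proximal_radius=1.0,
                             distal_radius=1.0, area_compliance=0.005,
                             n_grid_nodes=31)
        half2 = ArterySegment(id="b", name="b", length=30.0, proximal_radius=1.0,
                              distal_radius=1.0, area_compliance=0.005,
                              n_grid_nodes=31)
        split = ArterialTree(
            segments={"a": half, "b": half2}, topology={"a": ["b"]},
            terminals={"b": single.terminals["tube"]},
            sites={"aortic_root": ("a", 0.0)},
        )
        cfg = SolverConfig(conv_tol=1e-3, max_cycles=40)
        w1 = run_simulation(HEART, single, cfg).pressure("aortic_root")
        w2 = run_simulation(HEART, split, cfg).pressure("aortic_root")
        rms = np.sqrt(np.mean((w1.v - w2.v) ** 2))
        assert rms < 0.01 * w1.pulse()

    def test_occluded_branch_takes_no_mean_flow(self):
        main = ArterySegment(id="m", name="m", length=20.0, proximal_radius=1.0,
                             distal_radius=1.0, area_compliance=0.005,
                             n_grid_nodes=21)
        open_br = ArterySegment(id="o", name="o", length=15.0, proximal_radius=0.7,
                                distal_radius=0.7, area_compliance=0.002,
                                n_grid_nodes=16)
        shut_br = ArterySegment(id="s", name="s", length=15.0, proximal_radius=0.7,
                                distal_radius=0.7, area_compliance=0.002,
                                n_grid_nodes=16)
        tree = ArterialTree(
            segments={"m": main, "o": open_br, "s": shut_br},
            topology={"m": ["o", "s"]},
            terminals={
                "o": TerminalWindkessel(R1=0.2, R2=1.0, C=0.5, P_out=0.0),
                "s": TerminalWindkessel(R1=1e6, R2=1e6, C=1e-6, P_out=0.0),
            },
            sites={"aortic_root": ("m", 0.0), "open_end": ("o", 15.0),
                   "shut_end": ("s", 15.0)},
        )
        res = run_simulation(HEART, tree, SolverConfig(conv_tol=1e-3,
                                                       max_cycles=40))
        co = res.SV * HEART.HR / 60.0
        q_shut = np.mean(res.flow("shut_end").v)
        q_open = np.mean(res.flow("open_end").v)
        assert abs(q_shut) < 0.01 * co
        assert q_open == pytest.approx(co, rel=0.05)


class TestRunSimulation:
    def test_deterministic(self, fixture_tree):
        cfg = SolverConfig()
        a = run_simulation(HEART, fixture_tree, cfg)
        b = run_simulation(HEART, fixture_tree, cfg)
        assert np.array_equal(a.pressure("aortic_root").v,
                              b.pressure("aortic_root").v)
        assert np.array_equal(a.flow("radial").v, b.flow("radial").v)
        assert a.SV == b.SV

    def test_periodic_steady_state(self, fixture_tree):
        res = run_simulation(HEART, fixture_tree, SolverConfig())
        assert res.converged
        assert res.convergence_metric < SolverConfig.conv_tol
        assert res.V_cycle_gap < 0.5  # the P-V loop closes

    def test_dc_balance_map_equals_co_times_tvr(self, fixture_tree):
        res = run_simulation(HEART, fixture_tree, SolverConfig())
        agg = tree_aggregates(fixture_tree)
        co_mls = res.SV * HEART.HR / 60.0
        p_out = next(iter(fixture_tree.terminals.values())).P_out
        expected = co_mls * agg.TVR + p_out
        assert res.pressure("aortic_root").mean() == pytest.approx(
            expected, rel=0.05
        )

    def test_volume_conservation_per_cycle(self, fixture_tree):
        res = run_simulation(HEART, fixture_tree, SolverConfig())
        # ejected volume is the aortic-root flow integral by definition;
        # the loop closure bounds the residual stored in the ventricle
        assert res.V_cycle_gap < 0.01 * res.SV

    def test_flow_never_reverses_through_valve(self, fixture_tree):
        res = run_simulation(HEART, fixture_tree, SolverConfig())
        assert np.min(res.flow("aortic_root").v) >= 0.0

    def test_cfl_violation_names_segment(self, fixture_tree):
        state = build_state(fixture_tree, HEART, SolverConfig())
        state.dt *= 5.0
        with pytest.raises(CFLError, match="segment"):
            step_tree(state, 50)

    def test_end_systolic_point_lies_on_espvr(self, fixture_tree):
        from cvwaves.heart import espvr_pressure

        res = run_simulation(HEART, fixture_tree, SolverConfig())
        ratio = res.lv_P / (res.lv_V - HEART.Vd)
        i = int(np.argmax(ratio))
        assert res.lv_P[i] == pytest.approx(
            espvr_pressure(res.lv_V[i], HEART), abs=2.0
        )
        # stroke work (loop area) is positive for an ejecting beat
        assert -np.trapezoid(res.lv_P, res.lv_V) > 0

    def test_unconverged_flagged_not_silent(self, fixture_tree):
        res = run_simulation(HEART, fixture_tree,
                             SolverConfig(max_cycles=2, conv_tol=1e-9))
        assert not res.converged
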