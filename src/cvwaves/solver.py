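"""Coupled heart / 1D arterial-network solver.

The left ventricle (varying-elastance model, :mod:`cvwaves.heart`) is
coupled through a simplified Bernoulli-inertance aortic valve to a tree
of tapered 1D segments with a linear elastic wall law::

    A_t + Q_x = 0
    Q_t + (Q^2/A)_x + (A/rho) P_x = -k pi nu Q / A
    P  = P_ref + (A - A0(x)) / C'

integrated with a two-step (MacCormack) Lax-Wendroff scheme on each
segment grid. Segment ends are coupled by Riemann invariants of the
linear-wall system (W+- = u +- 2c, c = sqrt(A / (rho C'))): a Newton
solve per bifurcation enforces flow conservation and total-pressure
continuity, and each leaf is loaded by a three-element Windkessel.
Cycles are repeated until the aortic-root pressure is periodic.

Internally the kernel works in CGS units (dyn/cm^2, cm, s); the public
interface is mmHg / mL / s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .arterial import MMHG, NU, RHO, ArterialTree
from .heart import LVParameters, activation_curve, edpvr_pressure
from .waveform import Waveform

__all__ = [
    "SolverConfig",
    "ValveState",
    "SimulationResult",
    "run_simulation",
    "build_state",
    "step_tree",
    "junction_solve",
    "terminal_update",
    "valve_flow",
    "CFLError",
    "DivergenceError",
]


class CFLError(RuntimeError):
    """Time step violates the CFL condition on some segment."""


class DivergenceError(RuntimeError):
    """The integration produced non-finite values."""


@dataclass(frozen=True)
class SolverConfig:
    """Numerical configuration of the coupled simulation.

    The global time step is derived from the worst-case CFL condition
    over all grid cells with safety factor ``cfl_safety`` (checked at
    run time against the actual local wave speeds). Valve constants:
    ``valve_B`` (Bernoulli, mmHg s^2/mL^2) and ``valve_L`` (inertance,
    mmHg s^2/mL) describe a healthy, near-transparent valve. During
    diastole the ventricle refills from a constant-pressure venous
    source (pressure = EDPVR at the scenario EDV) through ``R_fill``.
    """

    sampling_rate: float = 1000.0   # Hz, output waveforms
    max_cycles: int = 30
    conv_tol: float = 0.005         # cycle-to-cycle RMS / PP
    cfl_safety: float = 0.8
    cfl_margin_pressure: float = 150.0  # mmHg used for the a-priori dt bound
    cfl_margin_velocity: float = 250.0  # cm/s used for the a-priori dt bound
    valve_B: float = 4.5e-5
    valve_L: float = 1.0e-3
    valve_K: float = 4.0    # leaflet opening/closing rate, 1/(mmHg s)
    R_fill: float = 0.01            # mmHg s/mL
    P_init: float = 80.0            # mmHg, initial arterial pressure
    P_ref: float = 90.0             # mmHg, pressure at which A = A0(x)


@dataclass
class ValveState:
    """Aortic valve state: open fraction and instantaneous flow."""

    open_fraction: float = 0.0
    Q_valve: float = 0.0

    def __post_init__(self) -> None:
        if self.Q_valve < 0:
            raise ValueError("no regurgitation: Q_valve must be >= 0")
        if self.open_fraction == 0.0 and self.Q_valve != 0.0:
            raise ValueError("closed valve must carry zero flow")


@dataclass
class SimulationResult:
    """One converged cardiac cycle at the configured sampling rate."""

    waveforms: dict[tuple[str, str], Waveform]
    lv_t: np.ndarray
    lv_V: np.ndarray
    lv_P: np.ndarray
    SV: float               # mL, integral of aortic-root flow over a cycle
    CO: float               # L/min
    EF: float               # SV / EDV
    period: float
    t_ejection_onset: float  # s from cycle start (valve opening)
    n_cycles_run: int
    converged: bool
    convergence_metric: float
    V_cycle_gap: float       # |V(0) - V(T)| of the last cycle, mL

    def pressure(self, site: str) -> Waveform:
        return self.waveforms[(site, "pressure")]

    def flow(self, site: str) -> Waveform:
        return self.waveforms[(site, "flow")]


# ======================================================================
# numba kernels (CGS internally)
# ======================================================================


@njit(cache=True)
def _c_of(A, A0, Cp, rho):
    return np.sqrt(A / (rho * Cp))


@njit(cache=True)
def _solve_dense(M, b):
    """Tiny in-place Gaussian elimination with partial pivoting."""
    n = b.shape[0]
    for k in range(n):
        piv = k
        best = abs(M[k, k])
        for i in range(k + 1, n):
            if abs(M[i, k]) > best:
                best = abs(M[i, k])
                piv = i
        if piv != k:
            for j in range(n):
                tmp = M[k, j]
                M[k, j] = M[piv, j]
                M[piv, j] = tmp
            tmp = b[k]
            b[k] = b[piv]
            b[piv] = tmp
        akk = M[k, k]
        for i in range(k + 1, n):
            f = M[i, k] / akk
            for j in range(k, n):
                M[i, j] -= f * M[k, j]
            b[i] -= f * b[k]
    for i in range(n - 1, -1, -1):
        s = b[i]
        for j in range(i + 1, n):
            s -= M[i, j] * b[j]
        b[i] = s / M[i, i]
    return b


@njit(cache=True)
def _junction_newton(Ap, up, W1p, A0p, Cpp, Ac, uc, W2c, A0c, Cpc, rho):
    """Coupled bifurcation solve.

    Unknowns z = [A_p, u_p, A_i, u_i ...]; equations: outgoing parent
    invariant, incoming child invariants, mass conservation, and
    total-pressure (P + rho u^2 / 2) continuity. Returns the updated
    values and a success flag.
    """
    m = Ac.shape[0]
    n = 2 + 2 * m
    z = np.empty(n)
    z[0] = Ap
    z[1] = up
    for i in range(m):
        z[2 + 2 * i] = Ac[i]
        z[3 + 2 * i] = uc[i]
    ok = False
    for _ in range(30):
        R = np.zeros(n)
        J = np.zeros((n, n))
        A_p = z[0]
        u_p = z[1]
        if A_p <= 0.0:
            return Ap, up, Ac, uc, False
        c_p = _c_of(A_p, A0p, Cpp, rho)
        # outgoing parent characteristic
        R[0] = u_p + 2.0 * c_p - W1p
        J[0, 0] = c_p / A_p
        J[0, 1] = 1.0
        # children incoming characteristics
        for i in range(m):
            A_i = z[2 + 2 * i]
            u_i = z[3 + 2 * i]
            if A_i <= 0.0:
                return Ap, up, Ac, uc, False
            c_i = _c_of(A_i, A0c[i], Cpc[i], rho)
            R[1 + i] = u_i - 2.0 * c_i - W2c[i]
            J[1 + i, 2 + 2 * i] = -c_i / A_i
            J[1 + i, 3 + 2 * i] = 1.0
        # mass conservation
        row = 1 + m
        s = A_p * u_p
        J[row, 0] = u_p
        J[row, 1] = A_p
        for i in range(m):
            A_i = z[2 + 2 * i]
            u_i = z[3 + 2 * i]
            s -= A_i * u_i
            J[row, 2 + 2 * i] = -u_i
            J[row, 3 + 2 * i] = -A_i
        R[row] = s
        # total pressure continuity parent vs each child
        Pp = (A_p - A0p) / Cpp + 0.5 * rho * u_p * u_p
        for i in range(m):
            A_i = z[2 + 2 * i]
            u_i = z[3 + 2 * i]
            Pi = (A_i - A0c[i]) / Cpc[i] + 0.5 * rho * u_i * u_i
            r = 2 + m + i
            R[r] = Pp - Pi
            J[r, 0] = 1.0 / Cpp
            J[r, 1] = rho * u_p
            J[r, 2 + 2 * i] = -1.0 / Cpc[i]
            J[r, 3 + 2 * i] = -rho * u_i
        dz = _solve_dense(J, R)
        for i in range(n):
            z[i] -= dz[i]
        # keep areas positive
        if z[0] <= 0.0:
            z[0] = 0.5 * Ap
        for i in range(m):
            if z[2 + 2 * i] <= 0.0:
                z[2 + 2 * i] = 0.5 * Ac[i]
        # step-based convergence: areas relative, velocities vs wave speed
        rel = abs(dz[1]) / c_p
        if abs(dz[0]) / z[0] > rel:
            rel = abs(dz[0]) / z[0]
        for i in range(m):
            ra = abs(dz[2 + 2 * i]) / z[2 + 2 * i]
            ru = abs(dz[3 + 2 * i]) / c_p
            if ra > rel:
                rel = ra
            if ru > rel:
                rel = ru
        if rel < 1e-10:
            ok = True
            break
    Anew = np.empty(m)
    unew = np.empty(m)
    for i in range(m):
        Anew[i] = z[2 + 2 * i]
        unew[i] = z[3 + 2 * i]
    return z[0], z[1], Anew, unew, ok


@njit(cache=True)
def _terminal_newton(W1, A_guess, A0, Cp, R1, Pwk_rel, rho):
    """Leaf boundary: (W1 - 2c(A)) * A = (P(A) - Pwk) / R1, solved for A.

    Pressures are relative to the reference (A = A0) level; ``Pwk_rel``
    is the Windkessel capacitor pressure on the same scale.
    """
    A = A_guess
    for _ in range(50):
        c = _c_of(A, A0, Cp, rho)
        P = (A - A0) / Cp
        F = (W1 - 2.0 * c) * A - (P - Pwk_rel) / R1
        dF = W1 - 3.0 * c - 1.0 / (R1 * Cp)
        step = F / dF
        A_new = A - step
        if A_new <= 0.0:
            A_new = 0.5 * A
        if abs(A_new - A) < 1e-12 * A0 + 1e-15:
            A = A_new
            break
        A = A_new
    return A


@njit(cache=True)
def _inlet_newton(Q_in, A_guess, A0, Cp, W2, rho):
    """Root inlet: Q_in / A - 2 c(A) = W2, solved for A."""
    A = A_guess
    for _ in range(50):
        c = _c_of(A, A0, Cp, rho)
        F = Q_in / A - 2.0 * c - W2
        dF = -Q_in / (A * A) - c / A
        A_new = A - F / dF
        if A_new <= 0.0:
            A_new = 0.5 * A
        if abs(A_new - A) < 1e-12 * A0 + 1e-15:
            A = A_new
            break
        A = A_new
    return A


@njit(cache=True)
def _advance(
    # node state
    A, Q,
    # node constants
    A0, dA0dx, Cp, fk,
    # segment layout
    seg_start, seg_n, seg_dx, seg_vol,
    # junctions (parent seg, child segs padded with -1)
    jn_parent, jn_children, jn_nchild,
    # terminals
    term_seg, term_R1, term_R2, term_C, term_Pout_rel, term_Pwk,
    # heart / valve: hp = [Ees, Vd, P0, beta, B, L, R_fill, P_ven, Pref]
    hp, eps_cycle, lv_state,  # lv_state = [V, Qv, open_flag]
    # bookkeeping
    rho, dt, step0, nsteps, cfl_limit,
    rec_nodes, recP, recQ, recLV,
):
    """Advance ``nsteps`` time steps; record at every step.

    Returns (status, step_count): status 0 = ok, s+1 = CFL violation on
    segment s, -1 = divergence. Pressures in recP are mmHg-relative to
    the reference added back by the caller; here CGS relative to A0.
    """
    nseg = seg_start.shape[0]
    n_cycle = eps_cycle.shape[0]
    nnodes = A.shape[0]
    Ap_ = np.empty(nnodes)
    Qp_ = np.empty(nnodes)
    Pn = np.empty(nnodes)
    # saved time-n boundary-adjacent values
    MMHG_ = 1333.22

    Ees = hp[0]
    Vd = hp[1]
    P0 = hp[2]
    beta = hp[3]
    Bv = hp[4]
    Lv = hp[5]
    R_fill = hp[6]
    P_ven = hp[7]
    Pref = hp[8]
    Kv = hp[9]

    root0 = seg_start[0]

    for it in range(nsteps):
        step = (step0 + it) % n_cycle
        # ---- CFL audit + pressure at time n
        for s in range(nseg):
            st = seg_start[s]
            nn = seg_n[s]
            dx = seg_dx[s]
            fastest = 0.0
            for j in range(st, st + nn):
                if not (A[j] > 0.0) or not np.isfinite(Q[j]):
                    return -1, it
                c = _c_of(A[j], A0[j], Cp[j], rho)
                sp = abs(Q[j] / A[j]) + c
                if sp > fastest:
                    fastest = sp
                Pn[j] = (A[j] - A0[j]) / Cp[j]
            if dt > cfl_limit * dx / fastest:
                return s + 1, it

        # ---- save time-n boundary neighborhood values (used by BCs)
        # (we only need nodes 0,1 and n-2,n-1 per segment; Pn already built)

        # ---- LV + valve (explicit, uses root pressure at time n)
        V = lv_state[0]
        Qv = lv_state[1]
        zeta = lv_state[2]   # valve open fraction
        eps = eps_cycle[step]
        P_lv = eps * Ees * (V - Vd) + (1.0 - eps) * P0 * np.exp(beta * V)
        P_root = Pref + Pn[root0] / MMHG_
        dP = P_lv - P_root
        # leaflet dynamics: the open fraction relaxes toward open (rate
        # ~ Kv * dP) while the pressure gradient is favourable, toward
        # closed otherwise; the effective orifice scales the Bernoulli
        # loss by 1/zeta^2
        if dP > 0.0:
            if zeta <= 0.0:
                zeta = 1e-3
            zeta = zeta + dt * Kv * (1.0 - zeta) * dP
        else:
            zeta = zeta + dt * Kv * zeta * dP
        if zeta > 1.0:
            zeta = 1.0
        if zeta < 0.0:
            zeta = 0.0
        if zeta > 1e-3:
            B_eff = Bv / (zeta * zeta)
            Qv = Qv + dt * (dP - B_eff * Qv * abs(Qv)) / Lv
            if Qv <= 0.0:
                Qv = 0.0
                if dP <= 0.0:
                    zeta = 0.0
        else:
            Qv = 0.0
            zeta = 0.0
        Q_fill = 0.0
        if P_ven > P_lv:
            Q_fill = (P_ven - P_lv) / R_fill
        V = V + dt * (Q_fill - Qv)
        lv_state[0] = V
        lv_state[1] = Qv
        lv_state[2] = zeta

        # ---- characteristic extrapolation (time n) for every boundary
        # left boundary of each segment: incoming W2 = u - 2c at foot
        # right boundary: outgoing W1 = u + 2c at foot
        W2L = np.empty(nseg)
        W1R = np.empty(nseg)
        qin_old = np.empty(nseg)
        qout_old = np.empty(nseg)
        for s in range(nseg):
            st = seg_start[s]
            nn = seg_n[s]
            dx = seg_dx[s]
            qin_old[s] = Q[st]
            qout_old[s] = Q[st + nn - 1]
            # left
            u0 = Q[st] / A[st]
            c0 = _c_of(A[st], A0[st], Cp[st], rho)
            th = (c0 - u0) * dt / dx
            if th < 0.0:
                th = 0.0
            if th > 1.0:
                th = 1.0
            Af = A[st] + th * (A[st + 1] - A[st])
            Qf = Q[st] + th * (Q[st + 1] - Q[st])
            dA0f = dA0dx[st] + th * (dA0dx[st + 1] - dA0dx[st])
            cf = _c_of(Af, Af, Cp[st], rho)
            # characteristic source: taper + friction act on u along the path
            src = dA0f / (rho * Cp[st]) - fk[st] * Qf / (Af * Af)
            W2L[s] = Qf / Af - 2.0 * cf + dt * src
            # right
            e = st + nn - 1
            ue = Q[e] / A[e]
            ce = _c_of(A[e], A0[e], Cp[e], rho)
            th = (ue + ce) * dt / dx
            if th < 0.0:
                th = 0.0
            if th > 1.0:
                th = 1.0
            Af = A[e] + th * (A[e - 1] - A[e])
            Qf = Q[e] + th * (Q[e - 1] - Q[e])
            dA0f = dA0dx[e] + th * (dA0dx[e - 1] - dA0dx[e])
            cf = _c_of(Af, Af, Cp[e], rho)
            src = dA0f / (rho * Cp[e]) - fk[e] * Qf / (Af * Af)
            W1R[s] = Qf / Af + 2.0 * cf + dt * src

        # ---- MacCormack interior update (conservative flux form:
        # F2 = Q^2/A + A^2/(2 rho C'), geometric taper source
        # (A / rho C') dA0/dx, exactly balanced at rest)
        for s in range(nseg):
            st = seg_start[s]
            nn = seg_n[s]
            dx = seg_dx[s]
            r = dt / dx
            # predictor (forward differences), j = st .. st+nn-2
            for j in range(st, st + nn - 1):
                f2a = Q[j] * Q[j] / A[j] + A[j] * A[j] / (2.0 * rho * Cp[j])
                f2b = (
                    Q[j + 1] * Q[j + 1] / A[j + 1]
                    + A[j + 1] * A[j + 1] / (2.0 * rho * Cp[j + 1])
                )
                Ap_[j] = A[j] - r * (Q[j + 1] - Q[j])
                Qp_[j] = (
                    Q[j]
                    - r * (f2b - f2a)
                    + dt * (A[j] / (rho * Cp[j])) * dA0dx[j]
                    - dt * fk[j] * Q[j] / A[j]
                )
            e = st + nn - 1
            Ap_[e] = A[e]
            Qp_[e] = Q[e]
            for j in range(st, st + nn):
                if Ap_[j] <= 0.0:
                    return -1, it
            # corrector (backward differences), j = st+1 .. st+nn-2
            for j in range(st + nn - 2, st, -1):
                f2a = (
                    Qp_[j - 1] * Qp_[j - 1] / Ap_[j - 1]
                    + Ap_[j - 1] * Ap_[j - 1] / (2.0 * rho * Cp[j - 1])
                )
                f2b = Qp_[j] * Qp_[j] / Ap_[j] + Ap_[j] * Ap_[j] / (2.0 * rho * Cp[j])
                Anew = 0.5 * (A[j] + Ap_[j] - r * (Qp_[j] - Qp_[j - 1]))
                Qnew = 0.5 * (
                    Q[j]
                    + Qp_[j]
                    - r * (f2b - f2a)
                    + dt * (Ap_[j] / (rho * Cp[j])) * dA0dx[j]
                    - dt * fk[j] * Qp_[j] / Ap_[j]
                )
                A[j] = Anew
                Q[j] = Qnew

        # ---- boundary conditions at time n+1
        # root inlet: prescribed valve flow
        Aroot = _inlet_newton(Qv, A[root0], A0[root0], Cp[root0], W2L[0], rho)
        A[root0] = Aroot
        Q[root0] = Qv

        # junctions
        for jn in range(jn_parent.shape[0]):
            ps = jn_parent[jn]
            pe = seg_start[ps] + seg_n[ps] - 1
            m = jn_nchild[jn]
            Ac = np.empty(m)
            uc = np.empty(m)
            W2c = np.empty(m)
            A0c = np.empty(m)
            Cpc = np.empty(m)
            for i in range(m):
                cs = jn_children[jn, i]
                cn = seg_start[cs]
                Ac[i] = A[cn]
                uc[i] = Q[cn] / A[cn]
                W2c[i] = W2L[cs]
                A0c[i] = A0[cn]
                Cpc[i] = Cp[cn]
            Apn, upn, Acn, ucn, ok = _junction_newton(
                A[pe], Q[pe] / A[pe], W1R[ps], A0[pe], Cp[pe],
                Ac, uc, W2c, A0c, Cpc, rho,
            )
            if not ok:
                return -1, it
            A[pe] = Apn
            Q[pe] = Apn * upn
            for i in range(m):
                cs = jn_children[jn, i]
                cn = seg_start[cs]
                A[cn] = Acn[i]
                Q[cn] = Acn[i] * ucn[i]

        # terminals
        for tt in range(term_seg.shape[0]):
            ts = term_seg[tt]
            e = seg_start[ts] + seg_n[ts] - 1
            At = _terminal_newton(
                W1R[ts], A[e], A0[e], Cp[e], term_R1[tt], term_Pwk[tt], rho
            )
            ct = _c_of(At, A0[e], Cp[e], rho)
            ut = W1R[ts] - 2.0 * ct
            A[e] = At
            Q[e] = At * ut
            # Windkessel capacitor update (semi-implicit)
            Qt = At * ut
            if term_R2[tt] > 0.0:
                a = dt / (term_R2[tt] * term_C[tt])
                term_Pwk[tt] = (
                    term_Pwk[tt] + dt * Qt / term_C[tt] + a * term_Pout_rel[tt]
                ) / (1.0 + a)
            else:
                term_Pwk[tt] = term_Pout_rel[tt]

        # ---- conservation correction: the characteristic boundary
        # overwrite is not flux-consistent with the interior scheme;
        # restore each segment's exact volume balance (trapezoidal
        # boundary fluxes) by spreading the residual over the interior
        # nodes. The residual is O(dx) per step and acts as a small
        # distributed area adjustment.
        for s in range(nseg):
            st = seg_start[s]
            nn = seg_n[s]
            dx = seg_dx[s]
            e = st + nn - 1
            vol = 0.5 * (A[st] + A[e])
            for j in range(st + 1, e):
                vol += A[j]
            vol *= dx
            target = seg_vol[s] + dt * 0.5 * (
                qin_old[s] + Q[st] - qout_old[s] - Q[e]
            )
            resid = target - vol
            dA = resid / (dx * (nn - 2))
            for j in range(st + 1, e):
                A[j] += dA
            seg_vol[s] = target

        # ---- record
        for k in range(rec_nodes.shape[0]):
            jj = rec_nodes[k]
            recP[it, k] = (A[jj] - A0[jj]) / Cp[jj]
            recQ[it, k] = Q[jj]
        recLV[it, 0] = lv_state[0]
        recLV[it, 1] = P_lv
        recLV[it, 2] = lv_state[1]

    return 0, nsteps


# ======================================================================
# Python-level state assembly and orchestration
# ======================================================================


@dataclass
class SimState:
    """Flattened solver state for one tree + heart configuration."""

    tree: ArterialTree
    heart: LVParameters
    config: SolverConfig
    seg_ids: list[str]
    A: np.ndarray
    Q: np.ndarray
    A0: np.ndarray
    dA0dx: np.ndarray
    Cp: np.ndarray        # CGS area compliance per cm
    fk: np.ndarray        # friction factor k*pi*nu per node
    seg_start: np.ndarray
    seg_n: np.ndarray
    seg_dx: np.ndarray
    seg_vol: np.ndarray
    jn_parent: np.ndarray
    jn_children: np.ndarray
    jn_nchild: np.ndarray
    term_seg: np.ndarray
    term_R1: np.ndarray
    term_R2: np.ndarray
    term_C: np.ndarray
    term_Pout_rel: np.ndarray
    term_Pwk: np.ndarray
    hp: np.ndarray
    eps_cycle: np.ndarray
    lv_state: np.ndarray
    dt: float
    n_steps: int
    rec_nodes: np.ndarray
    rec_names: list[str]
    step_count: int = 0

    def pressures_mmHg(self) -> np.ndarray:
        """Current nodal pressures (mmHg, absolute)."""
        return self.config.P_ref + (self.A - self.A0) / self.Cp / MMHG

    def step(self, n: int = 1) -> None:
        """Advance ``n`` solver steps of the global time step."""
        step_tree(self, n)


def build_state(
    tree: ArterialTree,
    heart: LVParameters,
    config: SolverConfig | None = None,
) -> SimState:
    """Discretize the tree and assemble the flattened solver state."""
    config = config or SolverConfig()
    tree.validate()
    root = tree.root
    # DFS order, root first
    order: list[str] = []
    stack = [root]
    while stack:
        sid = stack.pop()
        order.append(sid)
        stack.extend(reversed(tree.children(sid)))
    seg_index = {sid: i for i, sid in enumerate(order)}

    seg_start = np.zeros(len(order), dtype=np.int64)
    seg_n = np.zeros(len(order), dtype=np.int64)
    seg_dx = np.zeros(len(order))
    A0_parts, dA0_parts, Cp_parts, fk_parts = [], [], [], []
    pos = 0
    for i, sid in enumerate(order):
        seg = tree.segments[sid]
        n = seg.n_grid_nodes
        seg_start[i] = pos
        seg_n[i] = n
        seg_dx[i] = seg.length / (n - 1)
        x = np.linspace(0.0, seg.length, n)
        r = np.asarray(seg.radius_at(x), dtype=float)
        drdx = (seg.distal_radius - seg.proximal_radius) / seg.length
        A0_parts.append(np.pi * r ** 2)
        dA0_parts.append(2.0 * np.pi * r * drdx)
        Cp_parts.append(np.full(n, seg.area_compliance / MMHG))
        fk_parts.append(np.full(n, seg.wall_friction_coefficient * np.pi * NU))
        pos += n
    A0 = np.concatenate(A0_parts)
    dA0dx = np.concatenate(dA0_parts)
    Cp = np.concatenate(Cp_parts)
    fk = np.concatenate(fk_parts)

    junctions = [(sid, tree.children(sid)) for sid in order if tree.children(sid)]
    max_c = max((len(c) for _, c in junctions), default=1)
    jn_parent = np.array([seg_index[p] for p, _ in junctions], dtype=np.int64)
    jn_children = -np.ones((len(junctions), max(max_c, 1)), dtype=np.int64)
    jn_nchild = np.zeros(len(junctions), dtype=np.int64)
    for k, (_, cs) in enumerate(junctions):
        jn_nchild[k] = len(cs)
        for i, c in enumerate(cs):
            jn_children[k, i] = seg_index[c]

    leaves = [sid for sid in order if not tree.children(sid)]
    term_seg = np.array([seg_index[s] for s in leaves], dtype=np.int64)
    term_R1 = np.array([tree.terminals[s].R1 * MMHG for s in leaves])
    term_R2 = np.array([tree.terminals[s].R2 * MMHG for s in leaves])
    term_C = np.array([tree.terminals[s].C / MMHG for s in leaves])
    term_Pout_rel = np.array(
        [(tree.terminals[s].P_out - config.P_ref) * MMHG for s in leaves]
    )

    # initial state: uniform pressure P_init, zero flow
    dP0 = (config.P_init - config.P_ref) * MMHG
    A = A0 + dP0 * Cp
    Q = np.zeros_like(A)
    term_Pwk = np.full(len(leaves), dP0)
    seg_vol = np.empty(len(order))
    for i in range(len(order)):
        a, b = seg_start[i], seg_start[i] + seg_n[i] - 1
        seg_vol[i] = (0.5 * (A[a] + A[b]) + A[a + 1:b].sum()) * seg_dx[i]

    # heart coupling
    T = heart.period
    edv = heart.edv()
    p_ven = edpvr_pressure(edv, heart)
    hp = np.array([
        heart.Ees, heart.Vd, heart.P0, heart.beta,
        config.valve_B, config.valve_L, config.R_fill, p_ven, config.P_ref,
        config.valve_K,
    ])
    lv_state = np.array([edv, 0.0, 0.0])

    # global dt from worst-case CFL at elevated pressure/velocity
    dP_hi = (config.cfl_margin_pressure - config.P_ref) * MMHG
    A_hi = A0 + dP_hi * Cp
    c_hi = np.sqrt(A_hi / (RHO * Cp))
    dt_bound = np.inf
    for i in range(len(order)):
        sl = slice(seg_start[i], seg_start[i] + seg_n[i])
        fast = np.max(c_hi[sl]) + config.cfl_margin_velocity
        dt_bound = min(dt_bound, config.cfl_safety * seg_dx[i] / fast)
    n_steps = int(np.ceil(T / dt_bound))
    dt = T / n_steps

    # cached activation, one value per solver step
    tgrid = np.arange(n_steps) * dt
    tcurve, ecurve = activation_curve(T, heart, n=4096)
    eps_cycle = np.interp(tgrid, tcurve, ecurve, period=T)

    # record sites: always the root inlet node + every named site
    rec_nodes = [int(seg_start[0])]
    rec_names = ["aortic_root_inlet"]
    for name, (sid, x) in tree.sites.items():
        i = seg_index[sid]
        j = int(round(x / seg_dx[i]))
        j = min(max(j, 0), seg_n[i] - 1)
        rec_nodes.append(int(seg_start[i] + j))
        rec_names.append(name)
    return SimState(
        tree=tree, heart=heart, config=config, seg_ids=order,
        A=A, Q=Q, A0=A0, dA0dx=dA0dx, Cp=Cp, fk=fk,
        seg_start=seg_start, seg_n=seg_n, seg_dx=seg_dx, seg_vol=seg_vol,
        jn_parent=jn_parent, jn_children=jn_children, jn_nchild=jn_nchild,
        term_seg=term_seg, term_R1=term_R1, term_R2=term_R2, term_C=term_C,
        term_Pout_rel=term_Pout_rel, term_Pwk=term_Pwk,
        hp=hp, eps_cycle=eps_cycle, lv_state=lv_state,
        dt=dt, n_steps=n_steps,
        rec_nodes=np.array(rec_nodes, dtype=np.int64), rec_names=rec_names,
    )


def _run_steps(state: SimState, nsteps: int):
    recP = np.empty((nsteps, len(state.rec_nodes)))
    recQ = np.empty((nsteps, len(state.rec_nodes)))
    recLV = np.empty((nsteps, 3))
    status, done = _advance(
        state.A, state.Q,
        state.A0, state.dA0dx, state.Cp, state.fk,
        state.seg_start, state.seg_n, state.seg_dx, state.seg_vol,
        state.jn_parent, state.jn_children, state.jn_nchild,
        state.term_seg, state.term_R1, state.term_R2, state.term_C,
        state.term_Pout_rel, state.term_Pwk,
        state.hp, state.eps_cycle, state.lv_state,
        RHO, state.dt, state.step_count % state.n_steps, nsteps,
        state.config.cfl_safety,
        state.rec_nodes, recP, recQ, recLV,
    )
    if status > 0:
        raise CFLError(
            f"CFL violated on segment '{state.seg_ids[status - 1]}' at "
            f"step {state.step_count + done} (dt = {state.dt:.3e} s)"
        )
    if status < 0:
        raise DivergenceError(
            f"non-finite state at step {state.step_count + done}"
        )
    state.step_count += nsteps
    recP = state.config.P_ref + recP / MMHG
    return recP, recQ, recLV


def step_tree(state: SimState, n: int = 1):
    """Advance the coupled state ``n`` global time steps (in place)."""
    return _run_steps(state, n)


def run_simulation(
    heart: LVParameters,
    tree: ArterialTree,
    config: SolverConfig | None = None,
) -> SimulationResult:
    """Integrate whole cardiac cycles to a periodic steady state.

    Cycles are repeated until the cycle-to-cycle RMS difference of the
    aortic-root pressure is below ``config.conv_tol`` of its pulse
    pressure (or ``max_cycles`` is hit, in which case the result is
    flagged ``converged=False``). The last full cycle is returned,
    resampled at ``config.sampling_rate``.
    """
    config = config or SolverConfig()
    state = build_state(tree, heart, config)
    prev_root = None
    metric = np.inf
    converged = False
    n_cycles = 0
    recP = recQ = recLV = None
    for _ in range(config.max_cycles):
        recP, recQ, recLV = _run_steps(state, state.n_steps)
        n_cycles += 1
        root_p = recP[:, 0]
        if prev_root is not None:
            pp = float(np.max(root_p) - np.min(root_p))
            if pp > 0:
                metric = float(
                    np.sqrt(np.mean((root_p - prev_root) ** 2)) / pp
                )
                if metric < config.conv_tol:
                    converged = True
        prev_root = root_p
        if converged:
            break

    T = heart.period
    dt = state.dt
    t_sim = np.arange(state.n_steps) * dt
    fs = config.sampling_rate
    n_out = round(T * fs)
    t_out = np.arange(n_out) / fs

    # ejection onset: first step of the cycle with valve flow > 0
    qv = recLV[:, 2]
    open_idx = np.nonzero(qv > 0)[0]
    t_onset = float(t_sim[open_idx[0]]) if open_idx.size else float("nan")

    def _resample(y: np.ndarray) -> np.ndarray:
        return np.interp(t_out, t_sim, y, period=T)

    waveforms: dict[tuple[str, str], Waveform] = {}
    for k, name in enumerate(state.rec_names):
        for qty, arr, units in (
            ("pressure", recP[:, k], "mmHg"),
            ("flow", recQ[:, k], "mL/s"),
        ):
            waveforms[(name, qty)] = Waveform(
                site=name, t=t_out, v=_resample(arr),
                period=T, sampling_rate=fs, quantity=qty, units=units,
            )
    # canonical alias: "aortic_root" falls back to the inlet node when
    # the tree does not define the site explicitly
    if ("aortic_root", "pressure") not in waveforms:
        for qty in ("pressure", "flow"):
            w = waveforms[("aortic_root_inlet", qty)]
            waveforms[("aortic_root", qty)] = Waveform(
                site="aortic_root", t=w.t.copy(), v=w.v.copy(),
                period=T, sampling_rate=fs, quantity=qty, units=w.units,
            )

    q_root = recQ[:, 0]
    sv = float(np.sum(q_root) * dt)
    co = sv * heart.HR / 1000.0
    edv = state.heart.edv()
    v_gap = float(abs(recLV[-1, 0] - recLV[0, 0]))
    return SimulationResult(
        waveforms=waveforms,
        lv_t=t_out,
        lv_V=_resample(recLV[:, 0]),
        lv_P=_resample(recLV[:, 1]),
        SV=sv,
        CO=co,
        EF=sv / edv,
        period=T,
        t_ejection_onset=t_onset,
        n_cycles_run=n_cycles,
        converged=converged,
        convergence_metric=metric,
        V_cycle_gap=v_gap,
    )


# ======================================================================
# Small stand-alone operations (same kernels, test/analysis interface)
# ======================================================================


def junction_solve(
    parent_state: tuple[float, float, float, float, float],
    children_states: list[tuple[float, float, float, float, float]],
    rho: float = RHO,
):
    """One coupled junction solve.

    Each state is ``(A, u, W_invariant, A0, Cp_cgs)``: the parent
    supplies its outgoing invariant W+ = u + 2c, children their
    incoming W- = u - 2c. Returns ``((A_p, u_p), [(A_i, u_i), ...])``.
    """
    if not children_states:
        raise ValueError("junction needs at least one child")
    Ap, up, W1p, A0p, Cpp = parent_state
    Ac = np.array([s[0] for s in children_states])
    uc = np.array([s[1] for s in children_states])
    W2 = np.array([s[2] for s in children_states])
    A0c = np.array([s[3] for s in children_states])
    Cpc = np.array([s[4] for s in children_states])
    Apn, upn, Acn, ucn, ok = _junction_newton(
        Ap, up, W1p, A0p, Cpp, Ac, uc, W2, A0c, Cpc, rho
    )
    if not ok:
        raise RuntimeError("junction Newton iteration failed to converge")
    return (Apn, upn), list(zip(Acn, ucn))


def terminal_update(
    wk, P_stored: float, Q_in: float, dt: float
) -> tuple[float, float]:
    """Advance the Windkessel storage equation one step.

    ``P_stored`` is the capacitor pressure (mmHg); ``Q_in`` the inflow
    (mL/s). Returns ``(P_terminal, P_stored_new)`` where P_terminal =
    P_stored + Q_in * R1 is the pressure seen at the vessel end.
    """
    if wk.R2 > 0:
        a = dt / (wk.R2 * wk.C)
        p_new = (P_stored + dt * Q_in / wk.C + a * wk.P_out) / (1.0 + a)
    else:
        p_new = wk.P_out
    return P_stored + Q_in * wk.R1, p_new


def valve_flow(
    P_LV: float,
    P_root: float,
    state: ValveState,
    dt: float,
    B: float = SolverConfig.valve_B,
    L: float = SolverConfig.valve_L,
    K: float = SolverConfig.valve_K,
) -> ValveState:
    """Advance the simplified aortic valve one step.

    The open fraction follows first-order leaflet dynamics (opening
    rate K (1-z) dP under a favourable gradient, closing rate K z dP
    otherwise); while open, the transvalvular drop follows
    dP = (B / z^2) Q^2 + L dQ/dt, and the valve seals on flow reversal.
    No regurgitation is permitted.
    """
    zeta = state.open_fraction
    q = state.Q_valve
    dp = P_LV - P_root
    if dp > 0.0:
        if zeta <= 0.0:
            zeta = 1e-3
        zeta = min(zeta + dt * K * (1.0 - zeta) * dp, 1.0)
    else:
        zeta = max(zeta + dt * K * zeta * dp, 0.0)
    if zeta > 1e-3:
        q = q + dt * (dp - (B / zeta ** 2) * q * abs(q)) / L
        if q <= 0.0:
            return ValveState(open_fraction=0.0 if dp <= 0 else zeta, Q_valve=0.0)
        return ValveState(open_fraction=zeta, Q_valve=q)
    return ValveState(open_fraction=0.0, Q_valve=0.0)
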