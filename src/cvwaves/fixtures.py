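"""Synthetic inputs: the reduced fixture arterial tree and test waveforms.

``build_fixture_tree`` constructs a reduced arterial network — the
aorta, one arm path to the radial artery, and lumped side branches —
whose aggregate afterload matches prescribed targets for total vascular
resistance (TVR), total vascular compliance (TVC) and aortic-root
characteristic impedance (Zc), representative of a healthy middle-aged
adult. ``synth_waveform`` generates analytic pressure/flow waves with
closed-form feature ground truth for exercising the analysis modules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .arterial import (
    MMHG,
    RHO,
    ArterialTree,
    ArterySegment,
    TerminalWindkessel,
    tree_aggregates,
)
from .waveform import Waveform

__all__ = [
    "FixtureSpec",
    "SynthWaveSpec",
    "FixtureError",
    "build_fixture_tree",
    "synth_waveform",
]


class FixtureError(RuntimeError):
    """Fixture tuning failed; the message carries diagnostics."""


@dataclass(frozen=True)
class FixtureSpec:
    """Targets and layout options for the reduced fixture tree.

    Default targets are the afterload of a healthy middle-aged adult:
    TVR 1.22 mmHg s/mL, TVC 0.88 mL/mmHg (arterial + terminal), aortic
    Zc 0.04 mmHg s/mL. ``terminal_compliance_fraction`` fixes how much
    of TVC sits in the terminal Windkessels (0.26/0.88 by default).
    """

    n_aortic_segments: int = 5
    include_arm_path: bool = True
    target_TVR: float = 1.22
    target_TVC: float = 0.88
    target_Zc: float = 0.04
    terminal_compliance_fraction: float = 0.26 / 0.88
    random_seed: int = 0
    jitter: float = 0.0   # optional fractional jitter on branch radii
    # geometric blend of the arch compliance toward the root's value,
    # grading the proximal-to-distal aortic stiffening (0 = no grading)
    arch_blend: float = 0.65
    # terminal compliance ~ (bed conductance)^p: p > 1 makes the small
    # distal beds relatively stiff, which reproduces the textbook
    # aorta-to-radial pulse pressure amplification (~1.3-1.7)
    terminal_compliance_exponent: float = 1.5

    def __post_init__(self) -> None:
        if min(self.target_TVR, self.target_TVC, self.target_Zc) <= 0:
            raise ValueError("targets must be positive")
        if self.n_aortic_segments < 4:
            raise ValueError("need at least 4 aortic segments")
        if not (0.0 < self.terminal_compliance_fraction < 1.0):
            raise ValueError("terminal compliance fraction must be in (0,1)")


# Geometry table: (id, length cm, r_prox cm, r_dist cm, nominal wave
# speed cm/s, grid nodes). Radii are at the 90 mmHg reference pressure.
# The aortic path runs root -> iliac bifurcation; lumped side branches
# collect the head, viscera and legs; the arm path ends at the radial
# measurement site.
_AORTA = [
    ("asc_aorta", 5.0, 1.75, 1.62, None, 5),      # compliance set by Zc
    ("aortic_arch", 4.0, 1.62, 1.42, 500.0, 3),
    ("desc_thoracic_aorta", 19.0, 1.42, 1.10, 550.0, 9),
    ("abdominal_aorta", 15.0, 1.10, 0.87, 620.0, 7),
    ("infrarenal_aorta", 11.0, 0.87, 0.70, 680.0, 5),
]
_BRANCHES = [
    ("head_branches", 18.0, 0.50, 0.40, 750.0, 7),
    ("subclavian_axillary", 15.0, 0.45, 0.36, 800.0, 6),
    ("brachial", 24.0, 0.36, 0.26, 850.0, 9),
    ("radial", 24.0, 0.20, 0.17, 950.0, 9),
    ("ulnar", 24.0, 0.20, 0.17, 950.0, 9),
    ("visceral_branches", 7.0, 0.60, 0.50, 750.0, 4),
    ("iliac_femoral", 35.0, 0.70, 0.45, 850.0, 13),
]
_ARM_IDS = {"subclavian_axillary", "brachial", "radial", "ulnar"}

# Resting distribution of cardiac output among the terminal beds.
_FLOW_FRACTIONS = {
    "head_branches": 0.16,
    "radial": 0.022,
    "ulnar": 0.022,
    "visceral_branches": 0.42,
    "iliac_femoral": 0.376,
}


def _compliance_from_speed(r_mean: float, c: float) -> float:
    """Area compliance per cm (cm^2/mmHg) giving wave speed c at r_mean."""
    A = np.pi * r_mean ** 2
    return A * MMHG / (RHO * c ** 2)


def _subdivide(row, k: int):
    """Split an aorta row into k sub-rows with interpolated radii."""
    sid, L, rp, rd, c, n = row
    out = []
    for i in range(k):
        f0, f1 = i / k, (i + 1) / k
        r0 = rp + (rd - rp) * f0
        r1 = rp + (rd - rp) * f1
        nn = max(3, int(round(n / k)) + 1)
        out.append((f"{sid}_{i + 1}", L / k, r0, r1, c, nn))
    return out


def build_fixture_tree(spec: FixtureSpec | None = None) -> ArterialTree:
    """Build and tune the reduced fixture tree.

    Tuning is deterministic and proceeds in decoupled stages: the root
    segment compliance is fixed by the Zc target; branch compliances
    follow textbook wave speeds; the remaining aortic compliances are
    scaled to hit the arterial-compliance budget; terminal proximal
    resistances are set to each leaf's characteristic impedance
    (reflectionless at high frequency) and the distal resistances are
    root-found to hit the TVR target.
    """
    spec = spec or FixtureSpec()

    aorta_rows = list(_AORTA)
    extra = spec.n_aortic_segments - len(aorta_rows)
    if extra > 0:
        # refine the two longest thoracic/abdominal pieces first
        refine = ["desc_thoracic_aorta", "abdominal_aorta", "infrarenal_aorta"]
        rows = []
        for row in aorta_rows:
            if extra > 0 and row[0] in refine:
                k = min(1 + extra, 3)
                rows.extend(_subdivide(row, k))
                extra -= k - 1
            else:
                rows.append(row)
        aorta_rows = rows

    branch_rows = list(_BRANCHES)
    if not spec.include_arm_path:
        branch_rows = [r for r in branch_rows if r[0] not in _ARM_IDS]

    rng = np.random.default_rng(spec.random_seed)

    c_t_target = spec.target_TVC * spec.terminal_compliance_fraction
    c_a_target = spec.target_TVC - c_t_target

    # --- stage 1: root compliance from Zc (Zc = sqrt(rho/(MMHG A C')))
    root_row = aorta_rows[0]
    A_root = np.pi * root_row[2] ** 2
    cp_root = RHO / (MMHG * A_root * spec.target_Zc ** 2)
    c_root_total = cp_root * root_row[1]

    # --- stage 2: branch compliances from nominal wave speeds
    def _row_cp(row):
        _, L, rp, rd, c, _ = row
        jit = 1.0 + spec.jitter * rng.uniform(-1.0, 1.0) if spec.jitter else 1.0
        return _compliance_from_speed(0.5 * (rp + rd) * jit, c)

    branch_cp = {row[0]: _row_cp(row) for row in branch_rows}
    c_branch_total = sum(
        branch_cp[row[0]] * row[1] for row in branch_rows
    )

    # --- stage 3: scale remaining aortic compliances to the C_A budget.
    # Arch segments are geometrically blended toward the root compliance
    # (weight arch_blend) so the proximal aorta stiffens gradually; the
    # common scale s on the nominal profile is root-found to land the
    # total on the budget.
    rest_rows = aorta_rows[1:]
    rest_cp_nominal = {row[0]: _row_cp(row) for row in rest_rows}
    budget = c_a_target - c_root_total - c_branch_total
    if budget <= 0:
        raise FixtureError(
            "compliance budget infeasible: root + branch compliance "
            f"{c_root_total + c_branch_total:.3f} mL/mmHg exceeds the "
            f"arterial target {c_a_target:.3f} mL/mmHg"
        )
    arch_ids = {r[0] for r in rest_rows if r[0].startswith("aortic_arch")}
    w = spec.arch_blend

    def _rest_cp(row, s: float) -> float:
        cp = s * rest_cp_nominal[row[0]]
        if row[0] in arch_ids and w > 0:
            cp = cp_root ** w * cp ** (1.0 - w)
        return cp

    def _rest_total(s: float) -> float:
        return sum(_rest_cp(row, s) * row[1] for row in rest_rows)

    try:
        s = brentq(lambda x: _rest_total(x) - budget, 1e-4, 50.0, xtol=1e-12)
    except ValueError as exc:
        raise FixtureError(f"aortic compliance tuning failed: {exc}") from exc

    def _segment(row, cp):
        sid, L, rp, rd, _, n = row
        return ArterySegment(
            id=sid, name=sid.replace("_", " "), length=L,
            proximal_radius=rp, distal_radius=rd,
            area_compliance=cp, n_grid_nodes=n,
        )

    segments: dict[str, ArterySegment] = {}
    segments[root_row[0]] = _segment(root_row, cp_root)
    for row in rest_rows:
        segments[row[0]] = _segment(row, _rest_cp(row, s))
    for row in branch_rows:
        segments[row[0]] = _segment(row, branch_cp[row[0]])

    # --- topology: aortic chain with side branches at fixed stations
    aorta_ids = [row[0] for row in aorta_rows]
    topology: dict[str, list[str]] = {}
    for up, dn in zip(aorta_ids[:-1], aorta_ids[1:]):
        topology[up] = [dn]
    arch = aorta_ids[1]
    topology[arch] = list(topology.get(arch, []))
    if spec.include_arm_path:
        topology[arch] = ["head_branches", "subclavian_axillary"] + topology[arch]
        topology["subclavian_axillary"] = ["brachial"]
        topology["brachial"] = ["radial", "ulnar"]
    else:
        topology[arch] = ["head_branches"] + topology[arch]
    # visceral branches leave the last abdominal piece above the renals
    abd_ids = [i for i in aorta_ids if i.startswith("abdominal_aorta")]
    topology[abd_ids[-1]] = ["visceral_branches"] + topology.get(abd_ids[-1], [])
    last = aorta_ids[-1]
    topology[last] = ["iliac_femoral"]

    leaves = [sid for sid in segments if not topology.get(sid)]

    # --- stage 4: terminal loads; R1 = leaf characteristic impedance,
    # R2 scaled by a common factor to hit the TVR target
    fractions = dict(_FLOW_FRACTIONS)
    if not spec.include_arm_path:
        extra_f = fractions.pop("radial") + fractions.pop("ulnar")
        fractions["head_branches"] += extra_f
    total_f = sum(fractions[l] for l in leaves)
    fractions = {l: fractions[l] / total_f for l in leaves}

    r1 = {l: segments[l].char_impedance(segments[l].length) for l in leaves}
    p_c = spec.terminal_compliance_exponent
    cw = {l: fractions[l] ** p_c for l in leaves}
    cw_tot = sum(cw.values())
    c_term = {l: c_t_target * cw[l] / cw_tot for l in leaves}

    def _make_tree(lam: float) -> ArterialTree:
        terminals = {}
        for l in leaves:
            r_total = lam * spec.target_TVR / fractions[l]
            r2 = r_total - r1[l]
            if r2 <= 0:
                raise FixtureError(
                    f"terminal {l}: R2 = {r2:.3f} <= 0 at lambda = {lam:.3f}"
                )
            terminals[l] = TerminalWindkessel(
                R1=r1[l], R2=r2, C=c_term[l], P_out=0.0
            )
        sites = {"aortic_root": (aorta_ids[0], 0.0)}
        if spec.include_arm_path:
            sites["radial"] = ("radial", segments["radial"].length)
        return ArterialTree(
            segments=dict(segments), topology={k: list(v) for k, v in topology.items()},
            terminals=terminals, sites=sites,
        )

    def _tvr_gap(lam: float) -> float:
        return tree_aggregates(_make_tree(lam)).TVR - spec.target_TVR

    try:
        lam = brentq(_tvr_gap, 0.3, 3.0, xtol=1e-10)
    except Exception as exc:  # pragma: no cover - diagnostics path
        raise FixtureError(f"TVR tuning failed: {exc}") from exc

    tree = _make_tree(lam)
    agg = tree_aggregates(tree)
    checks = [
        ("TVR", agg.TVR, spec.target_TVR, 0.05),
        ("TVC", agg.TVC, spec.target_TVC, 0.05),
        ("Zc", agg.Zc_root, spec.target_Zc, 0.10),
    ]
    bad = [
        f"{k}: {v:.4f} vs target {t:.4f}"
        for k, v, t, tol in checks
        if abs(v - t) > tol * t
    ]
    if bad:
        raise FixtureError("fixture aggregates off target: " + "; ".join(bad))
    return tree


# ======================================================================
# Parametric test waveforms with closed-form ground truth
# ======================================================================


@dataclass(frozen=True)
class SynthWaveSpec:
    """Analytic test waveform specification.

    Kinds: ``flat`` (constant ``level``); ``two_peak`` (baseline plus
    two separated smooth pulses — peripheral-like); ``typeA`` (early
    shoulder, dominant late systolic peak); ``typeC`` (dominant early
    peak, late shoulder); ``flow`` (a single ejection-shaped pulse,
    mL/s). Pressure components are raised-cosine bumps of compact
    support (``width_*`` is the support half-width): with disjoint
    supports the peak amplitudes are exact, the wave is exactly
    periodic, and each bump's curvature changes sign at half its
    half-width from the center — closed-form inflection ground truth.
    """

    kind: str = "typeA"
    period: float = 60.0 / 70.0
    sampling_rate: float = 1000.0
    baseline: float = 70.0      # mmHg (DBP) or 0 for flow
    level: float = 90.0         # flat wave value
    amp_early: float = 20.0     # mmHg above baseline
    amp_late: float = 10.0
    t_early: float = 0.10       # s, early component center
    t_late: float = 0.28        # s, late component center
    width_early: float = 0.060  # s, support half-width
    width_late: float = 0.100   # s
    flow_amp: float = 450.0     # mL/s
    flow_onset: float = 0.05    # s
    flow_duration: float = 0.30 # s

    def __post_init__(self) -> None:
        if self.kind not in {"flat", "two_peak", "typeA", "typeC", "flow"}:
            raise ValueError(f"unknown waveform kind {self.kind!r}")
        if self.period <= 0:
            raise ValueError("period must be positive")
        if self.sampling_rate < 200:
            raise ValueError("sampling_rate must be at least 200 Hz")


def _periodic_bump(t: np.ndarray, t0: float, hw: float, T: float) -> np.ndarray:
    """Raised-cosine bump of unit height and compact support |t-t0| < hw."""
    d = np.mod(t - t0 + T / 2, T) - T / 2
    out = np.zeros_like(t)
    inside = np.abs(d) < hw
    out[inside] = np.cos(0.5 * np.pi * d[inside] / hw) ** 2
    return out


def synth_waveform(spec: SynthWaveSpec) -> tuple[Waveform, dict]:
    """Generate the analytic waveform and its ground-truth features."""
    T = spec.period
    fs = spec.sampling_rate
    n = round(T * fs)
    t = np.arange(n) / fs
    truth: dict[str, float | str | None] = {"kind": spec.kind}

    if spec.kind == "flat":
        v = np.full(n, spec.level)
        truth.update(SBP=spec.level, DBP=spec.level, PP=0.0, MAP=spec.level)
        quantity, units = "pressure", "mmHg"
    elif spec.kind == "flow":
        v = spec.flow_amp * np.clip(
            np.sin(np.pi * (t - spec.flow_onset) / spec.flow_duration), 0.0, None
        ) * ((t >= spec.flow_onset) & (t <= spec.flow_onset + spec.flow_duration))
        truth.update(
            Q_max=spec.flow_amp,
            t_peak=spec.flow_onset + spec.flow_duration / 2,
        )
        quantity, units = "flow", "mL/s"
    else:
        if spec.kind == "typeA":
            a1, a2 = spec.amp_early, max(spec.amp_late, spec.amp_early * 1.2)
        elif spec.kind == "typeC":
            a1, a2 = spec.amp_early, min(spec.amp_late, spec.amp_early * 0.6)
        else:  # two_peak: use amplitudes as given
            a1, a2 = spec.amp_early, spec.amp_late
        if spec.t_early + spec.width_early > spec.t_late - spec.width_late:
            raise ValueError("early and late components must not overlap")
        g1 = _periodic_bump(t, spec.t_early, spec.width_early, T)
        g2 = _periodic_bump(t, spec.t_late, spec.width_late, T)
        v = spec.baseline + a1 * g1 + a2 * g2
        sbp = spec.baseline + max(a1, a2)
        truth.update(
            SBP=sbp, DBP=spec.baseline, PP=sbp - spec.baseline,
            amp_early=a1, amp_late=a2,
            t_peak=spec.t_early if a1 >= a2 else spec.t_late,
            pAIx=100.0 * a2 / a1,
        )
        # shoulder ground truth: the raised-cosine curvature changes
        # sign (falling to rising) half a half-width past the early peak
        truth["t_inflection"] = spec.t_early + 0.5 * spec.width_early
        quantity, units = "pressure", "mmHg"

    wave = Waveform(
        site=f"synthetic_{spec.kind}", t=t, v=v, period=T,
        sampling_rate=fs, quantity=quantity, units=units,
    )
    return wave, truth
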