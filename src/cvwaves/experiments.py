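"""The paired-contractility study and its sensitivity variants.

High and low end-systolic elastance hearts eject into the *same*
arterial tree; preload (EDV, and through the EDPVR the EDP) is adjusted
by the Frank-Starling route so both scenarios deliver the same stroke
volume. Every waveform analysis of the pipeline is collected into a
summary report per scenario, and a set of directional checks encodes
the expected hemodynamic signature of raising contractility at constant
cardiac output and afterload.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .arterial import ArterialTree, scale_tree
from .heart import LVParameters
from .pwa import (
    basic_features,
    central_augmentation,
    peripheral_aix,
    pp_amplification,
)
from .solver import SimulationResult, SolverConfig, run_simulation
from .wavesep import (
    characteristic_impedance,
    input_impedance,
    separate_waves,
)

__all__ = [
    "PreloadPolicy",
    "ScenarioConfig",
    "SummaryReport",
    "ExperimentResult",
    "ExperimentError",
    "match_preload",
    "run_scenario",
    "run_contractility_experiment",
    "sensitivity_suite",
    "write_report",
    "read_report",
]


class ExperimentError(RuntimeError):
    """Preload matching or scenario execution failed."""


@dataclass(frozen=True)
class PreloadPolicy:
    """Either match stroke volume (mL) or fix the EDP (mmHg)."""

    kind: str          # "match_SV" | "fixed_EDP"
    value: float

    def __post_init__(self) -> None:
        if self.kind not in ("match_SV", "fixed_EDP"):
            raise ValueError(f"unknown preload policy {self.kind!r}")


@dataclass(frozen=True)
class ScenarioConfig:
    """One contractility scenario: heart + preload policy + perturbation."""

    label: str
    heart: LVParameters
    preload: PreloadPolicy
    perturbation: tuple[float, float] = (1.0, 1.0)  # compliance, resistance


@dataclass
class SummaryReport:
    """All waveform characteristics of one converged scenario."""

    label: str
    converged: bool
    # global
    SV: float
    CO: float
    EDV: float
    EDP: float
    EF: float
    # aortic flow
    Q_max: float
    t_Q_max: float
    dQdt_max: float
    # LV
    P_LV_max: float
    t_P_LV_max: float
    LV_dPdt_max: float
    # aortic pressure
    aortic_SBP: float
    aortic_DBP: float
    aortic_MAP: float
    aortic_PP: float
    aortic_AP: Optional[float]
    aortic_AIx: Optional[float]
    phenotype: str
    aortic_dPdt_max: float
    # radial pressure
    radial_SBP: float
    radial_DBP: float
    radial_MAP: float
    radial_PP: float
    radial_AIx: Optional[float]
    PP_amp: float
    # wave separation
    Zc: float
    amp_f: float
    amp_b: float
    peak_f: float
    peak_b: float
    t_peak_f: float
    t_peak_b: float
    slope_f_max: float
    slope_b_max: float
    reflection_coefficient: float

    def validate(self) -> None:
        """Internal consistency of the derived quantities."""
        assert abs(self.aortic_PP - (self.aortic_SBP - self.aortic_DBP)) < 1e-6
        if self.aortic_AIx is not None and self.aortic_AP is not None:
            assert abs(self.aortic_AIx - 100 * self.aortic_AP / self.aortic_PP) < 0.05
        assert abs(self.PP_amp - self.radial_PP / self.aortic_PP) < 1e-6


@dataclass
class ExperimentResult:
    """Paired scenario reports plus the directional check list."""

    report_high: SummaryReport
    report_low: SummaryReport
    checks: list[dict]
    tree_hash: str
    degenerate: bool = False

    @property
    def all_passed(self) -> bool:
        return all(c["passed"] for c in self.checks)


def _tree_hash(tree: ArterialTree) -> str:
    return hashlib.sha256(tree.to_json().encode()).hexdigest()[:16]


def match_preload(
    heart: LVParameters,
    tree: ArterialTree,
    target_SV: float,
    config: SolverConfig | None = None,
    bracket: tuple[float, float] = (60.0, 200.0),
    tol_mL: float = 0.5,
    max_iter: int = 25,
) -> tuple[LVParameters, SimulationResult, dict]:
    """Adjust EDV (EDP via the EDPVR) until the simulated SV hits target.

    The Frank-Starling direction (SV increasing in EDV) makes bisection
    on EDV safe. Two probe runs and a linear prediction pre-refine the
    bracket before bisecting — stroke volume is nearly linear in EDV —
    so the matcher typically needs 5-7 simulations. Returns the
    adjusted parameters, the matched simulation, and a diagnostics
    dict (final EDV, EDP, EF, simulation count).
    """
    config = config or SolverConfig()
    n_sims = 0

    def run_at(edv: float) -> SimulationResult:
        nonlocal n_sims
        n_sims += 1
        return run_simulation(heart.with_preload_edv(edv), tree, config)

    lo, hi = bracket
    edv0 = float(np.clip(heart.edv(), lo, hi))
    res0 = run_at(edv0)
    if abs(res0.SV - target_SV) <= tol_mL:
        h = heart.with_preload_edv(edv0)
        return h, res0, {
            "EDV": edv0, "EDP": h.edp(), "EF": res0.EF, "n_sims": n_sims,
        }
    # linear prediction (dSV/dEDV ~ 1 near the operating point)
    edv1 = float(np.clip(edv0 + (target_SV - res0.SV), lo, hi))
    res1 = run_at(edv1)
    dsv = res1.SV - res0.SV
    dedv = edv1 - edv0
    if abs(dedv) > 1e-9 and dsv / dedv > 0.05:
        edv_star = edv1 + (target_SV - res1.SV) * dedv / dsv
    else:
        edv_star = 0.5 * (lo + hi)
    a = float(np.clip(edv_star - 8.0, lo, hi))
    b = float(np.clip(edv_star + 8.0, lo, hi))

    res_a = run_at(a)
    res_b = run_at(b)
    if not (res_a.SV < target_SV < res_b.SV):
        a, b = lo, hi
        res_a = run_at(a)
        res_b = run_at(b)
        if not (res_a.SV < target_SV < res_b.SV):
            raise ExperimentError(
                f"cannot bracket SV = {target_SV} mL on EDV in "
                f"[{lo}, {hi}] (SV range [{res_a.SV:.1f}, {res_b.SV:.1f}])"
            )
    best = None
    for _ in range(max_iter):
        mid = 0.5 * (a + b)
        res = run_at(mid)
        best = (mid, res)
        if abs(res.SV - target_SV) <= tol_mL:
            break
        if res.SV < target_SV:
            a = mid
        else:
            b = mid
    else:
        raise ExperimentError(
            f"preload matching did not converge in {max_iter} bisections"
        )
    edv, res = best
    h = heart.with_preload_edv(edv)
    return h, res, {"EDV": edv, "EDP": h.edp(), "EF": res.EF, "n_sims": n_sims}


def summarize(label: str, res: SimulationResult, heart: LVParameters) -> SummaryReport:
    """Collect every waveform analysis for one simulation."""
    p = res.pressure("aortic_root")
    q = res.flow("aortic_root")
    pr = res.pressure("radial")
    on = res.t_ejection_onset

    fa = basic_features(p, on)
    fq = basic_features(q, on)
    cap, caix, phenotype = central_augmentation(p, on)
    paix = peripheral_aix(pr, on)
    fr = basic_features(pr, on)
    ppamp = pp_amplification(p, pr)
    zc = characteristic_impedance(input_impedance(p, q))
    ws = separate_waves(p, q, zc, on)

    # LV pressure course (same time base as the waveforms)
    lv = res.lv_P
    i_lv = int(np.argmax(lv))
    dt = 1.0 / p.sampling_rate
    lv_dpdt = float(np.max(np.gradient(lv, dt)))

    rep = SummaryReport(
        label=label,
        converged=res.converged,
        SV=res.SV,
        CO=res.CO,
        EDV=heart.edv(),
        EDP=heart.edp(),
        EF=res.EF,
        Q_max=float(np.max(q.v)),
        t_Q_max=fq.t_peak,
        dQdt_max=fq.dPdt_max,
        P_LV_max=float(lv[i_lv]),
        t_P_LV_max=(i_lv * dt - on) % res.period,
        LV_dPdt_max=lv_dpdt,
        aortic_SBP=fa.SBP,
        aortic_DBP=fa.DBP,
        aortic_MAP=fa.MAP,
        aortic_PP=fa.PP,
        aortic_AP=cap,
        aortic_AIx=caix,
        phenotype=phenotype,
        aortic_dPdt_max=fa.dPdt_max,
        radial_SBP=fr.SBP,
        radial_DBP=fr.DBP,
        radial_MAP=fr.MAP,
        radial_PP=fr.PP,
        radial_AIx=paix,
        PP_amp=ppamp,
        Zc=zc,
        amp_f=ws.amp_f,
        amp_b=ws.amp_b,
        peak_f=ws.peak_f,
        peak_b=ws.peak_b,
        t_peak_f=ws.t_peak_f,
        t_peak_b=ws.t_peak_b,
        slope_f_max=ws.slope_f_max,
        slope_b_max=ws.slope_b_max,
        reflection_coefficient=ws.reflection_coefficient,
    )
    rep.validate()
    return rep


def run_scenario(
    scenario: ScenarioConfig,
    tree: ArterialTree,
    config: SolverConfig | None = None,
) -> tuple[SummaryReport, SimulationResult, LVParameters]:
    """Run one scenario under its preload policy on the given tree."""
    config = config or SolverConfig()
    if scenario.perturbation != (1.0, 1.0):
        tree = scale_tree(tree, *scenario.perturbation)
    if scenario.preload.kind == "match_SV":
        heart, res, _info = match_preload(
            scenario.heart, tree, scenario.preload.value, config
        )
    else:
        heart = LVParameters(
            **{
                **{k: v for k, v in asdict(scenario.heart).items()},
                "EDV": None,
                "EDP": scenario.preload.value,
            }
        )
        res = run_simulation(heart, tree, config)
    return summarize(scenario.label, res, heart), res, heart


def _rel_gap(a: float, b: float) -> float:
    return abs(a - b) / (0.5 * (abs(a) + abs(b)))


def directional_checks(
    hi: SummaryReport, lo: SummaryReport, degenerate: bool = False
) -> list[dict]:
    """The expected signature of raising Ees at constant CO/afterload."""

    def chk(name, passed, vh, vl):
        return {
            "name": name,
            "passed": bool(passed) if not degenerate else True,
            "high": vh,
            "low": vl,
            "degenerate": degenerate,
        }

    out = [
        chk("max_aortic_flow_higher", hi.Q_max > lo.Q_max, hi.Q_max, lo.Q_max),
        chk("flow_peak_earlier", hi.t_Q_max < lo.t_Q_max, hi.t_Q_max, lo.t_Q_max),
        chk("lv_dpdt_max_higher", hi.LV_dPdt_max > lo.LV_dPdt_max,
            hi.LV_dPdt_max, lo.LV_dPdt_max),
        chk("aortic_dpdt_max_higher", hi.aortic_dPdt_max > lo.aortic_dPdt_max,
            hi.aortic_dPdt_max, lo.aortic_dPdt_max),
        chk("forward_peak_earlier", hi.t_peak_f < lo.t_peak_f,
            hi.t_peak_f, lo.t_peak_f),
        chk("forward_slope_higher", hi.slope_f_max > lo.slope_f_max,
            hi.slope_f_max, lo.slope_f_max),
        chk("amp_f_within_10pct", _rel_gap(hi.amp_f, lo.amp_f) <= 0.10,
            hi.amp_f, lo.amp_f),
        chk("amp_b_within_10pct", _rel_gap(hi.amp_b, lo.amp_b) <= 0.10,
            hi.amp_b, lo.amp_b),
        chk("reflection_within_10pct",
            _rel_gap(hi.reflection_coefficient, lo.reflection_coefficient) <= 0.10,
            hi.reflection_coefficient, lo.reflection_coefficient),
        chk("radial_sbp_higher", hi.radial_SBP > lo.radial_SBP,
            hi.radial_SBP, lo.radial_SBP),
        chk("radial_pp_higher", hi.radial_PP > lo.radial_PP,
            hi.radial_PP, lo.radial_PP),
        chk("pp_amp_higher", hi.PP_amp > lo.PP_amp, hi.PP_amp, lo.PP_amp),
        chk("caix_lower",
            hi.aortic_AIx is not None and lo.aortic_AIx is not None
            and hi.aortic_AIx < lo.aortic_AIx,
            hi.aortic_AIx, lo.aortic_AIx),
        chk("caix_high_negative",
            hi.aortic_AIx is not None and hi.aortic_AIx < 0.0,
            hi.aortic_AIx, None),
        chk("caix_low_type_a",
            lo.aortic_AIx is not None and lo.aortic_AIx > 12.0
            and lo.phenotype == "TypeA",
            None, lo.aortic_AIx),
        chk("paix_lower",
            hi.radial_AIx is not None and lo.radial_AIx is not None
            and hi.radial_AIx < lo.radial_AIx,
            hi.radial_AIx, lo.radial_AIx),
        chk("map_within_3pct", _rel_gap(hi.aortic_MAP, lo.aortic_MAP) <= 0.03,
            hi.aortic_MAP, lo.aortic_MAP),
        chk("co_within_2pct", _rel_gap(hi.CO, lo.CO) <= 0.02, hi.CO, lo.CO),
    ]
    return out


def run_contractility_experiment(
    scenario_high: ScenarioConfig,
    scenario_low: ScenarioConfig,
    tree: ArterialTree,
    config: SolverConfig | None = None,
) -> ExperimentResult:
    """Run the paired high/low-Ees experiment on one shared tree.

    Both scenarios must carry the same afterload perturbation (the tree
    is identical across the pair by construction; its hash is recorded).
    If either simulation fails to converge the checks are skipped.
    """
    if scenario_high.perturbation != scenario_low.perturbation:
        raise ExperimentError("scenarios must share the same afterload")
    rep_hi, res_hi, heart_hi = run_scenario(scenario_high, tree, config)
    rep_lo, res_lo, heart_lo = run_scenario(scenario_low, tree, config)
    working = scale_tree(tree, *scenario_high.perturbation) \
        if scenario_high.perturbation != (1.0, 1.0) else tree
    degenerate = heart_hi == heart_lo
    if not (res_hi.converged and res_lo.converged):
        checks = [{
            "name": "converged", "passed": False,
            "high": res_hi.converged, "low": res_lo.converged,
            "degenerate": degenerate,
        }]
    else:
        checks = directional_checks(rep_hi, rep_lo, degenerate=degenerate)
    return ExperimentResult(
        report_high=rep_hi,
        report_low=rep_lo,
        checks=checks,
        tree_hash=_tree_hash(working),
        degenerate=degenerate,
    )


def sensitivity_suite(
    scenario_high: ScenarioConfig,
    scenario_low: ScenarioConfig,
    tree: ArterialTree,
    config: SolverConfig | None = None,
    fixed_EDP: float = 11.0,
) -> dict[str, ExperimentResult | Exception]:
    """Afterload/preload robustness variants of the paired experiment.

    Five variants: fixed preload (EDP pinned for both hearts, no SV
    matching), compliance x0.8 / x1.2, resistance x0.8 / x1.2. Failures
    are isolated per variant and returned as the exception.
    """
    from dataclasses import replace as _rp

    variants: dict[str, tuple[ScenarioConfig, ScenarioConfig]] = {}
    fixed = PreloadPolicy("fixed_EDP", fixed_EDP)
    variants["fixed_preload"] = (
        _rp(scenario_high, preload=fixed, label=scenario_high.label + "_fixedEDP"),
        _rp(scenario_low, preload=fixed, label=scenario_low.label + "_fixedEDP"),
    )
    for tag, pert in [
        ("compliance_x0.8", (0.8, 1.0)),
        ("compliance_x1.2", (1.2, 1.0)),
        ("resistance_x0.8", (1.0, 0.8)),
        ("resistance_x1.2", (1.0, 1.2)),
    ]:
        variants[tag] = (
            _rp(scenario_high, perturbation=pert, label=f"{scenario_high.label}_{tag}"),
            _rp(scenario_low, perturbation=pert, label=f"{scenario_low.label}_{tag}"),
        )
    out: dict[str, ExperimentResult | Exception] = {}
    for tag, (sh, sl) in variants.items():
        try:
            out[tag] = run_contractility_experiment(sh, sl, tree, config)
        except Exception as exc:  # isolate per-variant failures
            out[tag] = exc
    return out


# ----------------------------------------------------------------------
# report I/O
# ----------------------------------------------------------------------


def write_report(
    result: ExperimentResult,
    outdir: str | Path,
    simulations: dict[str, SimulationResult] | None = None,
    seed: int | None = None,
    extra_manifest: dict | None = None,
) -> dict[str, Path]:
    """Write JSON + CSV report (Table-2 shaped), waveform CSVs, manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    payload = {
        "high": asdict(result.report_high),
        "low": asdict(result.report_low),
        "checks": result.checks,
        "tree_hash": result.tree_hash,
        "degenerate": result.degenerate,
    }
    jpath = outdir / "report.json"
    jpath.write_text(json.dumps(payload, indent=1, sort_keys=True))
    written["json"] = jpath

    rows = pd.DataFrame(
        {
            "parameter": list(asdict(result.report_high).keys()),
            "high_contractility": list(asdict(result.report_high).values()),
            "low_contractility": list(asdict(result.report_low).values()),
        }
    )
    cpath = outdir / "report.csv"
    rows.to_csv(cpath, index=False)
    written["csv"] = cpath

    if simulations:
        for tag, res in simulations.items():
            for (site, qty), w in res.waveforms.items():
                p = outdir / f"{tag}_{site}_{qty}.csv"
                w.to_csv(p)
                written[f"{tag}_{site}_{qty}"] = p

    manifest = {
        "package_version": _pkg_version,
        "tree_hash": result.tree_hash,
        "config_hash": hashlib.sha256(
            json.dumps(
                {"high": payload["high"], "low": payload["low"],
                 "tree": result.tree_hash},
                sort_keys=True,
            ).encode()
        ).hexdigest()[:16],
        "seed": seed,
    }
    if extra_manifest:
        manifest.update(extra_manifest)
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    written["manifest"] = mpath
    return written


def read_report(outdir: str | Path) -> dict:
    """Round-trip loader for :func:`write_report`'s JSON payload."""
    return json.loads((Path(outdir) / "report.json").read_text())
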