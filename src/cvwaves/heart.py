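"""Time-varying elastance model of the left ventricle.

Instantaneous LV pressure is an activation-weighted blend of two
pressure-volume relations::

    P_LV(V, t) = eps(t) * ESPVR(V) + (1 - eps(t)) * EDPVR(V)

where ``ESPVR(V) = Ees * (V - Vd)`` is the linear end-systolic relation
(slope Ees = contractility), ``EDPVR(V) = P0 * exp(beta * V)`` is the
exponential end-diastolic relation, and the activation ``eps(t)`` is a
normalized double-hill function of time within the cardiac cycle that
rises from 0 to 1 once per beat and falls back.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

import numpy as np

__all__ = [
    "LVParameters",
    "LVState",
    "CyclePhase",
    "activation_value",
    "activation_curve",
    "espvr_pressure",
    "edpvr_pressure",
    "lv_pressure",
]

# Double-hill constants of the canonical normalized-elastance shape
# (contraction exponent/time constant, relaxation exponent/time constant;
# time constants are fractions of the cardiac period).
DEFAULT_ACT_M1 = 1.32
DEFAULT_ACT_M2 = 27.4
DEFAULT_ACT_TAU1 = 0.269
DEFAULT_ACT_TAU2 = 0.452


class CyclePhase(str, Enum):
    FILLING = "filling"
    ISOVOLUMIC = "isovolumic"
    EJECTION = "ejection"


@dataclass(frozen=True)
class LVParameters:
    """Left-ventricular parameters.

    Units: Ees mmHg/mL; Vd mL; P0 mmHg; beta 1/mL; HR bpm. Activation
    time constants are fractions of the cardiac period. Preload is
    specified as EDV (mL) and/or EDP (mmHg); when both are given they
    must be consistent through the EDPVR within 0.2 mmHg.
    """

    Ees: float
    Vd: float
    P0: float = 2.3
    beta: float = 0.013
    HR: float = 70.0
    act_m1: float = DEFAULT_ACT_M1
    act_m2: float = DEFAULT_ACT_M2
    act_tau1: float = DEFAULT_ACT_TAU1
    act_tau2: float = DEFAULT_ACT_TAU2
    EDV: float | None = None
    EDP: float | None = None

    def __post_init__(self) -> None:
        if self.Ees <= 0:
            raise ValueError("Ees must be positive")
        if self.P0 <= 0:
            raise ValueError("P0 must be positive")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.HR <= 0:
            raise ValueError("HR must be positive")
        if self.act_m1 <= 0 or self.act_m2 <= 0:
            raise ValueError("activation exponents must be positive")
        if not (0.0 < self.act_tau1 < self.act_tau2 < 1.0):
            raise ValueError("require 0 < act_tau1 < act_tau2 < 1")
        if self.EDV is None and self.EDP is None:
            raise ValueError("preload required: give EDV and/or EDP")
        if self.EDV is not None and self.EDP is not None:
            implied = edpvr_pressure(self.EDV, self)
            if abs(implied - self.EDP) > 0.2:
                raise ValueError(
                    f"inconsistent preload: EDPVR({self.EDV} mL) = "
                    f"{implied:.2f} mmHg but EDP = {self.EDP} mmHg "
                    "(must agree within 0.2 mmHg)"
                )

    @property
    def period(self) -> float:
        """Cardiac period in seconds."""
        return 60.0 / self.HR

    def edv(self) -> float:
        """End-diastolic volume (mL), derived from EDP if not given."""
        if self.EDV is not None:
            return float(self.EDV)
        return float(np.log(self.EDP / self.P0) / self.beta)

    def edp(self) -> float:
        """End-diastolic pressure (mmHg), derived from EDV if not given."""
        if self.EDP is not None:
            return float(self.EDP)
        return edpvr_pressure(self.EDV, self)

    def with_preload_edv(self, edv: float) -> "LVParameters":
        """Copy with preload re-specified by EDV (EDP derived)."""
        return replace(self, EDV=float(edv), EDP=None)


@dataclass
class LVState:
    """Instantaneous LV state used by the coupled simulation."""

    t: float
    V_LV: float
    P_LV: float
    phase: CyclePhase = CyclePhase.FILLING

    def __post_init__(self) -> None:
        if self.V_LV <= 0:
            raise ValueError("V_LV must be positive")
        if not np.isfinite(self.P_LV):
            raise ValueError("P_LV must be finite")


def _double_hill_raw(t: np.ndarray, T: float, p: LVParameters) -> np.ndarray:
    tau1 = p.act_tau1 * T
    tau2 = p.act_tau2 * T
    x1 = (t / tau1) ** p.act_m1
    x2 = (t / tau2) ** p.act_m2
    return (x1 / (1.0 + x1)) * (1.0 / (1.0 + x2))


def activation_curve(T: float, params: LVParameters, n: int = 2048) -> tuple[np.ndarray, np.ndarray]:
    """Activation eps(t) sampled on a uniform grid over one cycle.

    Returns ``(t, eps)`` with eps normalized so that max eps = 1. The
    curve is computed once per cycle and interpolated by the solver.
    """
    t = np.linspace(0.0, T, n, endpoint=False)
    raw = _double_hill_raw(t, T, params)
    return t, raw / raw.max()


def activation_value(t: float, T: float, params: LVParameters) -> float:
    """Activation eps at time ``t`` within a cycle of period ``T``.

    eps(0) = 0 and the maximum over the cycle is 1 after normalization.
    Raises ValueError if t lies outside [0, T).
    """
    if not (0.0 <= t < T):
        raise ValueError(f"t = {t} outside cardiac cycle [0, {T})")
    grid_t = np.linspace(0.0, T, 2048, endpoint=False)
    raw_max = _double_hill_raw(grid_t, T, params).max()
    return float(_double_hill_raw(np.asarray([t]), T, params)[0] / raw_max)


def espvr_pressure(V: float | np.ndarray, params: LVParameters) -> float | np.ndarray:
    """End-systolic pressure-volume relation: Ees * (V - Vd), mmHg."""
    out = params.Ees * (np.asarray(V, dtype=float) - params.Vd)
    return float(out) if np.ndim(V) == 0 else out


def edpvr_pressure(V: float | np.ndarray, params: LVParameters) -> float | np.ndarray:
    """End-diastolic pressure-volume relation: P0 * exp(beta * V), mmHg."""
    out = params.P0 * np.exp(params.beta * np.asarray(V, dtype=float))
    return float(out) if np.ndim(V) == 0 else out


def lv_pressure(
    V: float | np.ndarray,
    t: float,
    T: float,
    params: LVParameters,
    eps: float | None = None,
) -> float | np.ndarray:
    """Instantaneous LV pressure (mmHg) at volume ``V`` and cycle time ``t``.

    ``eps`` may be supplied directly (e.g. from a cached activation
    curve) to avoid recomputing the double-hill normalization.
    """
    if eps is None:
        eps = activation_value(t, T, params)
    return eps * espvr_pressure(V, params) + (1.0 - eps) * edpvr_pressure(V, params)
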