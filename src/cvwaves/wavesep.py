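"""Wave separation analysis.

Splits an aortic pressure wave into forward- and backward-travelling
components using the characteristic impedance estimated from the input
impedance spectrum: Zc is the mean modulus of Z_k = P_k / Q_k over
harmonics 3-9, and the linear decomposition is

    Pf = (dP + Zc dQ) / 2,   Pb = (dP - Zc dQ) / 2

applied to the pulsatile parts (the mean pressure is split equally
between the components, so Pf + Pb = P pointwise). The reflection
coefficient is the backward-to-forward amplitude ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pwa import _smooth_deriv
from .waveform import Waveform

__all__ = [
    "ImpedanceSpectrum",
    "WaveSeparation",
    "input_impedance",
    "characteristic_impedance",
    "separate_waves",
    "reflection_coefficient",
]


@dataclass
class ImpedanceSpectrum:
    """Input impedance per harmonic of the cardiac frequency."""

    k: np.ndarray          # harmonic index, 0 = DC
    freq: np.ndarray       # Hz
    modulus: np.ndarray    # mmHg s/mL
    phase: np.ndarray      # rad
    usable: np.ndarray     # bool: flow harmonic above tolerance

    def __post_init__(self) -> None:
        if np.any(self.modulus[self.usable] < 0):
            raise ValueError("impedance modulus must be non-negative")


@dataclass
class WaveSeparation:
    """Forward/backward components and the derived wave metrics."""

    Zc: float
    Pf: Waveform
    Pb: Waveform
    amp_f: float           # mmHg, max - min of the forward component
    amp_b: float
    peak_f: float          # mmHg, max value
    peak_b: float
    t_peak_f: float        # s from ejection onset
    t_peak_b: float
    slope_f_max: float     # mmHg/s
    slope_b_max: float
    reflection_coefficient: float  # %


def input_impedance(
    P: Waveform, Q: Waveform, rel_tol: float = 1e-9
) -> ImpedanceSpectrum:
    """Fourier-domain input impedance Z_k = P_k / Q_k over one period.

    Exactly one period is transformed (no windowing or padding — the
    waves are periodic). Harmonics whose flow coefficient modulus falls
    below ``rel_tol`` times the largest pulsatile flow harmonic are
    flagged unusable rather than divided through.
    """
    if P.n != Q.n or abs(P.period - Q.period) > 1e-12:
        raise ValueError("P and Q must share sampling and period")
    pk = np.fft.rfft(P.v) / P.n
    qk = np.fft.rfft(Q.v) / Q.n
    k = np.arange(len(pk))
    qmag = np.abs(qk)
    scale = np.max(qmag[1:]) if len(qmag) > 1 else qmag[0]
    usable = qmag > rel_tol * max(scale, 1e-300)
    z = np.full(len(pk), np.nan + 0j)
    z[usable] = pk[usable] / qk[usable]
    return ImpedanceSpectrum(
        k=k,
        freq=k / P.period,
        modulus=np.abs(z),
        phase=np.angle(z),
        usable=usable,
    )


def characteristic_impedance(
    spec: ImpedanceSpectrum, k_lo: int = 3, k_hi: int = 9
) -> float:
    """Mean input-impedance modulus over harmonics ``k_lo..k_hi``."""
    sel = (spec.k >= k_lo) & (spec.k <= k_hi)
    if not np.all(spec.usable[sel]):
        bad = spec.k[sel & ~spec.usable].tolist()
        raise ValueError(f"harmonics unusable for Zc estimation: {bad}")
    return float(np.mean(spec.modulus[sel]))


def separate_waves(
    P: Waveform,
    Q: Waveform,
    Zc: float,
    ejection_onset_s: float = 0.0,
) -> WaveSeparation:
    """Linear forward/backward decomposition of an aortic pressure wave."""
    if Zc <= 0:
        raise ValueError("Zc must be positive")
    if P.n != Q.n or abs(P.period - Q.period) > 1e-12:
        raise ValueError("P and Q must share sampling and period")
    p_mean = float(np.mean(P.v))
    q_mean = float(np.mean(Q.v))
    dp = P.v - p_mean
    dq = Q.v - q_mean
    pf = 0.5 * p_mean + 0.5 * (dp + Zc * dq)
    pb = P.v - pf

    def _wave(vals: np.ndarray, tag: str) -> Waveform:
        return Waveform(
            site=f"{P.site}_{tag}", t=P.t.copy(), v=vals, period=P.period,
            sampling_rate=P.sampling_rate, quantity="pressure", units="mmHg",
        )

    Pf = _wave(pf, "forward")
    Pb = _wave(pb, "backward")
    amp_f = Pf.pulse()
    amp_b = Pb.pulse()
    t_peak_f = (float(P.t[np.argmax(pf)]) - ejection_onset_s) % P.period
    t_peak_b = (float(P.t[np.argmax(pb)]) - ejection_onset_s) % P.period
    slope_f = float(np.max(_smooth_deriv(Pf, 1))) if amp_f > 0 else 0.0
    slope_b = float(np.max(_smooth_deriv(Pb, 1))) if amp_b > 0 else 0.0
    return WaveSeparation(
        Zc=Zc,
        Pf=Pf,
        Pb=Pb,
        amp_f=amp_f,
        amp_b=amp_b,
        peak_f=float(np.max(pf)),
        peak_b=float(np.max(pb)),
        t_peak_f=t_peak_f,
        t_peak_b=t_peak_b,
        slope_f_max=slope_f,
        slope_b_max=slope_b,
        reflection_coefficient=reflection_coefficient(amp_b, amp_f),
    )


def reflection_coefficient(amp_b: float, amp_f: float) -> float:
    """Backward-to-forward wave amplitude ratio, %."""
    if amp_f <= 0:
        raise ValueError("forward amplitude must be positive")
    return 100.0 * amp_b / amp_f
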