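"""Pulse wave analysis: pressure/flow waveform feature extraction.

Extracts systolic/diastolic/mean/pulse values, maximal upstroke slope,
the systolic inflection ("shoulder") point, central augmentation
pressure and index with Murgo Type A / Type C phenotyping, peripheral
(radial) augmentation index, and aorta-to-radial pulse pressure
amplification.

Derivatives are taken on a least-squares polynomial (Savitzky-Golay)
smoothed copy of the periodic waveform; the smoothing window (default
30 ms) bounds the timing resolution of every detected landmark.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .waveform import Waveform

__all__ = [
    "PWAFeatures",
    "basic_features",
    "ejection_onset",
    "find_inflection",
    "central_augmentation",
    "peripheral_aix",
    "pp_amplification",
    "SMOOTH_WINDOW_S",
]

SMOOTH_WINDOW_S = 0.030   # Savitzky-Golay window, s
SMOOTH_ORDER = 3
SYSTOLE_FRACTION = 0.45   # systolic search window as fraction of period


@dataclass
class PWAFeatures:
    """Waveform features; fields that need extra inputs stay None."""

    SBP: float
    DBP: float
    MAP: float
    PP: float
    dPdt_max: float
    t_peak: float                      # s from ejection onset
    t_inflection: Optional[float] = None
    cAP: Optional[float] = None
    cAIx: Optional[float] = None       # %
    phenotype: Optional[str] = None    # "TypeA" | "TypeC" | "Intermediate"
    pAIx: Optional[float] = None       # %
    PP_amp: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.DBP <= self.MAP <= self.SBP):
            raise ValueError("require DBP <= MAP <= SBP")
        if self.PP < 0:
            raise ValueError("PP must be non-negative")


def _window_samples(w: Waveform, seconds: float = SMOOTH_WINDOW_S) -> int:
    n = int(round(seconds * w.sampling_rate))
    n = max(n, SMOOTH_ORDER + 2)
    if n % 2 == 0:
        n += 1
    return min(n, w.n - 1 if (w.n - 1) % 2 == 1 else w.n - 2)

def _smooth_deriv(w: Waveform, deriv: int, window_s: float = SMOOTH_WINDOW_S,
                  order: int = SMOOTH_ORDER) -> np.ndarray:
    """Savitzky-Golay smoothed derivative on the periodic signal."""
    win = _window_samples(w, window_s)
    return savgol_filter(w.v, win, order, deriv=deriv, delta=w.dt, mode="wrap")


def ejection_onset(w: Waveform) -> float:
    """Foot of the upstroke by the intersecting-tangent method.

    The tangent at the point of maximal slope is intersected with the
    horizontal line through the diastolic minimum.
    """
    d1 = _smooth_deriv(w, 1)
    i = int(np.argmax(d1))
    slope = d1[i]
    if slope <= 0:
        raise ValueError("waveform has no rising edge")
    dbp = float(np.min(w.v))
    t_foot = w.t[i] - (w.v[i] - dbp) / slope
    return float(t_foot % w.period)


def basic_features(w: Waveform, ejection_onset_s: float | None = None) -> PWAFeatures:
    """Extremal/mean values and the maximal upstroke slope.

    ``t_peak`` is reported relative to ``ejection_onset_s`` (detected by
    the intersecting-tangent method when not supplied); for a flat wave
    it is 0 by convention.
    """
    v = w.v
    sbp = float(np.max(v))
    dbp = float(np.min(v))
    if sbp - dbp < 1e-12:
        return PWAFeatures(SBP=sbp, DBP=dbp, MAP=float(np.mean(v)),
                           PP=sbp - dbp, dPdt_max=0.0, t_peak=0.0)
    if ejection_onset_s is None:
        ejection_onset_s = ejection_onset(w)
    d1 = _smooth_deriv(w, 1)
    t_peak = (float(w.t[np.argmax(v)]) - ejection_onset_s) % w.period
    return PWAFeatures(
        SBP=sbp,
        DBP=dbp,
        MAP=float(np.mean(v)),
        PP=sbp - dbp,
        dPdt_max=float(np.max(d1)),
        t_peak=t_peak,
    )


def _rotated(w: Waveform, onset: float) -> tuple[np.ndarray, int]:
    """Values rotated so index 0 sits at the ejection onset."""
    i0 = int(round(onset * w.sampling_rate)) % w.n
    return np.roll(w.v, -i0), i0


def find_inflection(
    w: Waveform,
    ejection_onset_s: float | None = None,
    window_s: float = SMOOTH_WINDOW_S,
) -> Optional[float]:
    """Systolic inflection ("shoulder") time, s from ejection onset.

    The shoulder is the first falling-to-rising zero crossing of the
    smoothed second derivative after the point of maximal upstroke
    slope, within the systolic window. A crossing only counts as a
    shoulder when a genuine secondary wave follows: at the end of the
    positive-curvature stretch the pressure must still sit well above
    the diastolic level (> 25% of pulse pressure) — the decaying tail
    of a single smooth pulse relaxes to baseline instead and yields
    ``None`` ("no shoulder").
    """
    if ejection_onset_s is None:
        ejection_onset_s = ejection_onset(w)
    d1 = np.roll(_smooth_deriv(w, 1, window_s), 0)
    d2 = _smooth_deriv(w, 2, window_s)
    v, i0 = _rotated(w, ejection_onset_s)
    d1 = np.roll(d1, -i0)
    d2 = np.roll(d2, -i0)
    n_sys = int(SYSTOLE_FRACTION * w.n)
    pp = float(np.max(w.v) - np.min(w.v))
    if pp <= 0:
        return None
    i_up = int(np.argmax(d1[:n_sys]))
    dbp = float(np.min(w.v))
    level_floor = dbp + 0.25 * pp

    i = i_up + 1
    while i < n_sys - 1:
        if d2[i] < 0.0 <= d2[i + 1]:
            # candidate crossing (linear interpolation inside the step)
            frac = -d2[i] / (d2[i + 1] - d2[i])
            t_cross = (i + frac) * w.dt
            # find end of the positive-curvature stretch
            j = i + 1
            while j < n_sys and d2[j] >= 0.0:
                j += 1
            if v[min(j, n_sys - 1)] > level_floor:
                return float(t_cross)
            i = j
        else:
            i += 1
    return None


def central_augmentation(
    w: Waveform,
    ejection_onset_s: float | None = None,
) -> tuple[Optional[float], Optional[float], str]:
    """Central augmentation pressure (mmHg), index (%), and phenotype.

    With the systolic peak after the shoulder (late systolic peak), the
    augmentation is cAP = SBP - P(shoulder) > 0; with the peak before a
    late shoulder, cAP = P(shoulder) - SBP < 0. Phenotypes follow the
    Murgo classification: Type A when the peak follows the shoulder and
    cAIx > 12 %, Type C when the peak precedes the inflection and
    cAIx < 0, Intermediate otherwise (including "no shoulder").
    """
    if ejection_onset_s is None:
        ejection_onset_s = ejection_onset(w)
    t_infl = find_inflection(w, ejection_onset_s)
    if t_infl is None:
        return None, None, "Intermediate"
    v, _ = _rotated(w, ejection_onset_s)
    sbp = float(np.max(w.v))
    dbp = float(np.min(w.v))
    pp = sbp - dbp
    if pp <= 0:
        return None, None, "Intermediate"
    n_sys = int(SYSTOLE_FRACTION * w.n)
    t_peak = float(np.argmax(v[:n_sys])) * w.dt
    p_infl = float(np.interp(t_infl, np.arange(w.n) * w.dt, v))
    if t_peak > t_infl:
        cap = sbp - p_infl
    else:
        cap = p_infl - sbp
    caix = 100.0 * cap / pp
    if t_peak > t_infl and caix > 12.0:
        phenotype = "TypeA"
    elif t_peak < t_infl and caix < 0.0:
        phenotype = "TypeC"
    else:
        phenotype = "Intermediate"
    return cap, caix, phenotype


def peripheral_aix(
    w: Waveform,
    ejection_onset_s: float | None = None,
) -> Optional[float]:
    """Peripheral (radial) augmentation index, %.

    Ratio of the late to the early systolic peak amplitude, both
    measured above the diastolic minimum. The late feature is a local
    maximum after the early peak or, failing that, the late shoulder
    located by the curvature criterion. Returns ``None`` when no late
    systolic feature exists (single-peak wave).
    """
    if ejection_onset_s is None:
        ejection_onset_s = ejection_onset(w)
    v, i0 = _rotated(w, ejection_onset_s)
    dbp = float(np.min(w.v))
    pp = float(np.max(w.v)) - dbp
    if pp <= 0:
        return None
    win = _window_samples(w)
    vs = savgol_filter(v, win, SMOOTH_ORDER, mode="wrap")
    n_sys = int(SYSTOLE_FRACTION * w.n)
    peaks, _props = find_peaks(vs[:n_sys], prominence=0.005 * pp)
    if len(peaks) >= 2:
        early = float(v[peaks[0]]) - dbp
        late = float(v[peaks[-1]]) - dbp
        if early <= 0:
            return None
        return 100.0 * late / early
    # single peak: an early or late shoulder must stand in for the
    # missing extremum; otherwise the wave has no late systolic feature
    t_infl = find_inflection(w, ejection_onset_s)
    if t_infl is None or not len(peaks):
        return None
    i_peak = int(peaks[0])
    t_grid = np.arange(w.n) * w.dt
    p_infl = float(np.interp(t_infl, t_grid, v))
    t_peak_s = i_peak * w.dt
    if t_infl < t_peak_s:
        # shoulder on the upstroke: early feature, dominant late peak
        early, late = p_infl - dbp, float(v[i_peak]) - dbp
    else:
        early, late = float(v[i_peak]) - dbp, p_infl - dbp
    if early <= 0:
        return None
    return 100.0 * late / early


def pp_amplification(aortic: Waveform, radial: Waveform) -> float:
    """Pulse pressure amplification PP_radial / PP_aortic."""
    if abs(aortic.period - radial.period) > 1e-9:
        raise ValueError("waveforms must share the same period")
    pp_a = aortic.pulse()
    if pp_a <= 0:
        raise ValueError("aortic pulse pressure is zero")
    return radial.pulse() / pp_a
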