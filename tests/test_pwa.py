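"""Pulse wave analysis against generator ground truth and invariances."""

import numpy as np
import pytest

from cvwaves.fixtures import SynthWaveSpec, synth_waveform
from cvwaves.pwa import (
    SMOOTH_WINDOW_S,
    basic_features,
    central_augmentation,
    ejection_onset,
    find_inflection,
    peripheral_aix,
    pp_amplification,
)
from cvwaves.waveform import Waveform


def _wave(kind, **kw):
    return synth_waveform(SynthWaveSpec(kind=kind, **kw))


class TestBasicFeatures:
    def test_flat_wave(self):
        w, _ = _wave("flat", level=90.0)
        f = basic_features(w)
        assert f.SBP == f.DBP == f.MAP == 90.0
        assert f.PP == 0.0
        assert f.dPdt_max == 0.0

    @pytest.mark.parametrize("kind", ["typeA", "typeC", "two_peak"])
    def test_extrema_match_ground_truth(self, kind):
        w, truth = _wave(kind)
        f = basic_features(w)
        assert f.SBP == pytest.approx(truth["SBP"], abs=1e-9)
        assert f.DBP == pytest.approx(truth["DBP"], abs=1e-9)
        assert f.PP == pytest.approx(truth["PP"], abs=1e-9)

    def test_flow_peak(self):
        w, truth = _wave("flow")
        f = basic_features(w, ejection_onset_s=0.05)
        assert np.max(w.v) == pytest.approx(truth["Q_max"], rel=1e-4)
        assert f.t_peak + 0.05 == pytest.approx(truth["t_peak"], abs=0.005)

    def test_nonuniform_sampling_rejected(self):
        t = np.linspace(0, 1, 100, endpoint=False) ** 1.1
        with pytest.raises(ValueError):
            Waveform(site="x", t=t, v=np.ones(100), period=1.0,
                     sampling_rate=100.0)


class TestInflection:
    def test_type_a_shoulder_recovered(self):
        w, truth = _wave("typeA")
        on = ejection_onset(w)
        t = find_inflection(w, on)
        assert t is not None
        assert t + on == pytest.approx(truth["t_inflection"], abs=0.01)

    def test_type_c_shoulder_after_peak(self):
        w, truth = _wave("typeC")
        on = ejection_onset(w)
        t = find_inflection(w, on)
        f = basic_features(w, on)
        assert t is not None
        assert t > f.t_peak

    def test_single_pulse_has_no_shoulder(self):
        w, _ = _wave("two_peak", amp_late=0.0)
        assert find_inflection(w) is None

    def test_timing_within_smoothing_window(self):
        # detected landmark errors stay below one smoothing-window width
        for t_early in (0.08, 0.12, 0.16):
            w, truth = _wave("typeA", t_early=t_early,
                             t_late=t_early + 0.22)
            on = ejection_onset(w)
            t = find_inflection(w, on)
            assert abs(t + on - truth["t_inflection"]) < SMOOTH_WINDOW_S


class TestAugmentation:
    def test_type_a_positive(self):
        w, truth = _wave("typeA")
        cap, caix, phenotype = central_augmentation(w)
        assert cap > 0
        assert caix > 12.0
        assert phenotype == "TypeA"

    def test_type_c_negative(self):
        w, _ = _wave("typeC")
        cap, caix, phenotype = central_augmentation(w)
        assert cap < 0
        assert caix < 0.0
        assert phenotype == "TypeC"

    def test_no_shoulder_is_intermediate(self):
        w, _ = _wave("two_peak", amp_late=0.0)
        cap, caix, phenotype = central_augmentation(w)
        assert cap is None and caix is None
        assert phenotype == "Intermediate"

    def test_caix_is_cap_over_pp(self):
        w, truth = _wave("typeA")
        cap, caix, _ = central_augmentation(w)
        assert caix == pytest.approx(100.0 * cap / truth["PP"])


class TestPeripheralAIx:
    @pytest.mark.parametrize("a1,a2,expected", [
        (20.0, 10.0, 50.0),
        (20.0, 20.0, 100.0),
        (25.0, 5.0, 20.0),
    ])
    def test_two_peak_ratio(self, a1, a2, expected):
        w, _ = _wave("two_peak", amp_early=a1, amp_late=a2)
        assert peripheral_aix(w) == pytest.approx(expected, abs=0.5)

    def test_single_peak_undefined(self):
        w, _ = _wave("two_peak", amp_late=0.0)
        assert peripheral_aix(w) is None


class TestPPAmplification:
    def test_identical_waves(self):
        w, _ = _wave("typeA")
        assert pp_amplification(w, w) == pytest.approx(1.0)

    def test_ratio_from_ground_truth(self):
        a, ta = _wave("typeA", amp_early=20.0, amp_late=26.0)
        r, tr = _wave("two_peak", amp_early=40.0, amp_late=12.0)
        assert pp_amplification(a, r) == pytest.approx(
            tr["PP"] / ta["PP"], rel=1e-9
        )

    def test_zero_aortic_pp_rejected(self):
        flat, _ = _wave("flat")
        w, _ = _wave("typeA")
        with pytest.raises(ValueError):
            pp_amplification(flat, w)


class TestInvariances:
    def test_pressure_offset(self):
        w, _ = _wave("typeA")
        shifted = Waveform(site=w.site, t=w.t, v=w.v + 10.0, period=w.period,
                           sampling_rate=w.sampling_rate)
        f0, f1 = basic_features(w), basic_features(shifted)
        assert f1.SBP == pytest.approx(f0.SBP + 10.0)
        assert f1.DBP == pytest.approx(f0.DBP + 10.0)
        assert f1.MAP == pytest.approx(f0.MAP + 10.0)
        assert f1.PP == pytest.approx(f0.PP)
        _, c0, p0 = central_augmentation(w)
        _, c1, p1 = central_augmentation(shifted)
        assert c1 == pytest.approx(c0, abs=1e-6)
        assert p0 == p1

    def test_circular_shift_with_consistent_onset(self):
        w, _ = _wave("typeA")
        on = ejection_onset(w)
        n_shift = 150
        rolled = w.shifted(n_shift)
        on_rolled = (on + n_shift * w.dt) % w.period
        f0 = basic_features(w, on)
        f1 = basic_features(rolled, on_rolled)
        assert f1.SBP == pytest.approx(f0.SBP)
        assert f1.t_peak == pytest.approx(f0.t_peak, abs=2 * w.dt)
        t0 = find_inflection(w, on)
        t1 = find_inflection(rolled, on_rolled)
        assert t1 == pytest.approx(t0, abs=2 * w.dt)
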