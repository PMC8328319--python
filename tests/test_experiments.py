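"""Paired contractility experiment: preload matching, checks, reports."""

import numpy as np
import pytest

from cvwaves import (
    LVParameters,
    PreloadPolicy,
    ScenarioConfig,
    run_contractility_experiment,
    run_simulation,
)
from cvwaves.experiments import (
    ExperimentError,
    match_preload,
    read_report,
    run_scenario,
    write_report,
)
from cvwaves.solver import SolverConfig
from cvwaves.waveform import Waveform

CFG = SolverConfig()


class TestMatchPreload:
    def test_converges_to_target_sv(self, paired_experiment):
        for rep in (paired_experiment.report_high, paired_experiment.report_low):
            assert rep.SV == pytest.approx(65.0, abs=0.5)

    def test_fixed_point_returns_parameters_unchanged(self, fixture_tree,
                                                      heart_high):
        base = run_simulation(heart_high, fixture_tree, CFG)
        h, res, info = match_preload(heart_high, fixture_tree, base.SV, CFG)
        assert info["EDV"] == pytest.approx(heart_high.edv(), abs=0.5)
        assert info["n_sims"] == 1

    def test_frank_starling_direction(self, fixture_tree, heart_high):
        # lowering Ees at fixed EDV strictly lowers stroke volume
        weaker = LVParameters(Ees=1.0, Vd=heart_high.Vd, EDV=heart_high.EDV)
        sv_strong = run_simulation(heart_high, fixture_tree, CFG).SV
        sv_weak = run_simulation(weaker, fixture_tree, CFG).SV
        assert sv_weak < sv_strong

    def test_unreachable_target_raises(self, fixture_tree, heart_high):
        with pytest.raises(ExperimentError, match="bracket"):
            match_preload(heart_high, fixture_tree, 500.0, CFG,
                          bracket=(60.0, 200.0))


class TestPairedExperiment:
    def test_reports_internally_consistent(self, paired_experiment):
        for rep in (paired_experiment.report_high, paired_experiment.report_low):
            rep.validate()
            assert rep.converged

    def test_constant_cardiac_output_premise(self, paired_experiment):
        hi, lo = paired_experiment.report_high, paired_experiment.report_low
        assert hi.CO == pytest.approx(lo.CO, rel=0.02)

    def test_low_ef_matches_dilated_ventricle(self, paired_experiment):
        # the low-contractility heart dilates to hold SV: EF must drop
        hi, lo = paired_experiment.report_high, paired_experiment.report_low
        assert lo.EDV > hi.EDV
        assert lo.EF < hi.EF

    def test_core_mechanism_directions(self, paired_experiment):
        """Raising Ees at constant SV: faster, earlier forward wave;
        higher peripheral pulse pressure; lower augmentation."""
        by_name = {c["name"]: c for c in paired_experiment.checks}
        for name in (
            "max_aortic_flow_higher",
            "flow_peak_earlier",
            "aortic_dpdt_max_higher",
            "forward_peak_earlier",
            "forward_slope_higher",
            "pp_amp_higher",
            "caix_lower",
            "paix_lower",
            "map_within_3pct",
        ):
            assert by_name[name]["passed"], by_name[name]

    def test_mismatched_afterload_rejected(self, scenario_pair, fixture_tree):
        hi, lo = scenario_pair
        from dataclasses import replace
        bad = replace(lo, perturbation=(0.8, 1.0))
        with pytest.raises(ExperimentError, match="afterload"):
            run_contractility_experiment(hi, bad, fixture_tree, CFG)

    def test_degenerate_self_comparison(self, fixture_tree, heart_high):
        sc = ScenarioConfig("same", heart_high, PreloadPolicy("fixed_EDP", 8.2))
        exp = run_contractility_experiment(sc, sc, fixture_tree, CFG)
        assert exp.degenerate
        assert all(c["degenerate"] for c in exp.checks)
        assert exp.report_high.SV == pytest.approx(exp.report_low.SV, abs=1e-9)

    def test_identity_perturbation_equals_base(self, scenario_pair,
                                               fixture_tree, paired_experiment):
        from dataclasses import asdict, replace
        hi, lo = scenario_pair
        hi1 = replace(hi, perturbation=(1.0, 1.0))
        lo1 = replace(lo, perturbation=(1.0, 1.0))
        exp = run_contractility_experiment(hi1, lo1, fixture_tree, CFG)
        assert asdict(exp.report_high) == asdict(paired_experiment.report_high)
        assert asdict(exp.report_low) == asdict(paired_experiment.report_low)


class TestSensitivity:
    def test_all_variants_complete(self, sensitivity_results):
        assert set(sensitivity_results) == {
            "fixed_preload", "compliance_x0.8", "compliance_x1.2",
            "resistance_x0.8", "resistance_x1.2",
        }
        for tag, result in sensitivity_results.items():
            assert not isinstance(result, Exception), (tag, result)

    def test_resistance_up_raises_map_in_both(self, sensitivity_results,
                                              paired_experiment):
        up = sensitivity_results["resistance_x1.2"]
        assert up.report_high.aortic_MAP > paired_experiment.report_high.aortic_MAP
        assert up.report_low.aortic_MAP > paired_experiment.report_low.aortic_MAP

    def test_fixed_preload_pins_edp(self, sensitivity_results):
        fp = sensitivity_results["fixed_preload"]
        assert fp.report_high.EDP == pytest.approx(11.0, abs=1e-9)
        assert fp.report_low.EDP == pytest.approx(11.0, abs=1e-9)


class TestReportIO:
    def test_round_trip(self, paired_experiment, tmp_path):
        write_report(paired_experiment, tmp_path)
        back = read_report(tmp_path)
        from dataclasses import asdict
        assert back["high"] == asdict(paired_experiment.report_high)
        assert back["low"] == asdict(paired_experiment.report_low)
        assert back["checks"] == paired_experiment.checks

    def test_manifest_hash_tracks_config(self, paired_experiment,
                                         sensitivity_results, tmp_path):
        import json
        a = tmp_path / "a"
        b = tmp_path / "b"
        c = tmp_path / "c"
        write_report(paired_experiment, a)
        write_report(paired_experiment, b)
        write_report(sensitivity_results["resistance_x1.2"], c)
        ha = json.loads((a / "manifest.json").read_text())["config_hash"]
        hb = json.loads((b / "manifest.json").read_text())["config_hash"]
        hc = json.loads((c / "manifest.json").read_text())["config_hash"]
        assert ha == hb
        assert ha != hc

    def test_waveform_csv_round_trip(self, fixture_tree, heart_high, tmp_path):
        res = run_simulation(heart_high, fixture_tree, CFG)
        w = res.pressure("aortic_root")
        path = tmp_path / "p.csv"
        w.to_csv(path)
        back = Waveform.from_csv(path)
        assert back.site == w.site
        assert back.period == pytest.approx(w.period)
        assert np.allclose(back.v, w.v, rtol=1e-7, atol=1e-7)
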