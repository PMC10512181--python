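"""Dysfunction scaling, beat metrics and protocol plumbing."""

import numpy as np
import pytest

from triseg.experiments import (DysfunctionSpec, JOULE_PER_MMHG_ML,
                                _loop_area, _ventricle_metrics,
                                apply_dysfunction, cardiac_metrics,
                                septal_curvature_timecourse)
from triseg.sarcomere import WallProperties

PROPS = {"LW": WallProperties(500.0, 1700.0),
         "SW": WallProperties(500.0, 1700.0),
         "RW": WallProperties(150.0, 2200.0)}


class TestApplyDysfunction:
    def test_lv_systolic_moderate_scales_lw_and_sw(self):
        out = apply_dysfunction(PROPS, DysfunctionSpec("LV", "systolic",
                                                       "moderate"))
        assert out["LW"].k_act == pytest.approx(0.6 * 1700.0)
        assert out["SW"].k_act == pytest.approx(0.6 * 1700.0)
        assert out["RW"].k_act == PROPS["RW"].k_act
        assert out["LW"].k_pas == PROPS["LW"].k_pas

    def test_rv_diastolic_severe_scales_rw_only(self):
        out = apply_dysfunction(PROPS, DysfunctionSpec("RV", "diastolic",
                                                       "severe"))
        assert out["RW"].k_pas == pytest.approx(15.0 * 150.0)
        assert out["RW"].k_act == PROPS["RW"].k_act
        assert out["LW"] == PROPS["LW"] and out["SW"] == PROPS["SW"]

    def test_healthy_severity_is_identity(self):
        out = apply_dysfunction(PROPS, DysfunctionSpec("LV", "diastolic",
                                                       "healthy"))
        assert out == PROPS

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            DysfunctionSpec("LA", "systolic", "moderate")


class TestBeatMetrics:
    def _elliptical_loop(self, v0=78.0, a=34.0, p0=51.0, b=49.0, n=2000):
        """Counterclockwise ellipse in the (V, P) plane, area pi a b."""
        th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        return p0 + b * np.sin(th), v0 - a * np.cos(th)

    def test_loop_area_of_ellipse(self):
        p, v = self._elliptical_loop()
        assert abs(_loop_area(p, v)) == pytest.approx(np.pi * 34.0 * 49.0,
                                                      rel=1e-4)

    def test_metric_identities(self):
        p, v = self._elliptical_loop()
        m = _ventricle_metrics(p, v, hr=60.0)
        assert m.EDV == pytest.approx(112.0)
        assert m.ESV == pytest.approx(44.0)
        assert m.SV == pytest.approx(m.EDV - m.ESV)
        assert m.EF == pytest.approx(100.0 * m.SV / m.EDV)
        assert m.CO == pytest.approx(m.SV * 60.0 / 1000.0)

    def test_cpo_rectangle_oracle(self):
        """A rectangular loop spanning 2-100 mmHg and 44-112 mL at 60 bpm
        holds (100-2) x 68 mmHg mL of work: CPO = area x HR."""
        v = np.concatenate([np.linspace(44, 112, 500),           # fill at 2
                            np.full(100, 112.0),                 # isovolumic
                            np.linspace(112, 44, 500),           # eject at 100
                            np.full(100, 44.0)])
        p = np.concatenate([np.full(500, 2.0),
                            np.linspace(2, 100, 100),
                            np.full(500, 100.0),
                            np.linspace(100, 2, 100)])
        m = _ventricle_metrics(p, v, hr=60.0)
        expected = 98.0 * 68.0 * JOULE_PER_MMHG_ML * 1.0
        assert m.CPO == pytest.approx(expected, rel=2e-2)
        assert m.EDP == pytest.approx(2.0, abs=0.5)
        assert m.ESP == pytest.approx(100.0, abs=0.5)

    def test_corner_extraction_ignores_isovolumic_pressure_swing(self):
        """EDP comes from the filling corner even though pressure rises
        sharply while volume stays at its maximum."""
        v = np.concatenate([np.linspace(44, 112, 400),
                            np.full(200, 112.0),
                            np.linspace(112, 44, 400)])
        p = np.concatenate([np.full(400, 3.0),
                            np.linspace(3.0, 90.0, 200),   # isovolumic rise
                            np.full(400, 90.0)])
        m = _ventricle_metrics(p, v, hr=60.0)
        assert m.EDP == pytest.approx(3.0, abs=0.5)

    def test_zero_stroke_volume_degenerate(self):
        p = np.full(100, 10.0)
        v = np.full(100, 80.0)
        m = _ventricle_metrics(p, v, hr=60.0)
        assert m.SV == 0.0 and m.EF == 0.0
        assert m.CPO == pytest.approx(0.0, abs=1e-12)


class TestVolumeLoading:
    def test_sweep_monotone_filling_and_frank_starling(self, healthy_model):
        """Along a loading sweep EDP rises with volume and SV does not fall
        with EDP (Frank-Starling)."""
        import warnings
        from triseg.experiments import volume_loading_sweep
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sweep = volume_loading_sweep(healthy_model,
                                         fractions=(0.92, 1.0, 1.08),
                                         n_transient=12, n_record=1)
        df = sweep.frame()
        assert not df["failed"].any()
        assert df["mean_Psa"].is_monotonic_increasing
        fs = sweep.frank_starling("LV")
        assert np.all(np.diff(fs[:, 0]) > 0)        # EDP rises
        assert np.all(np.diff(fs[:, 1]) > -1e-6)    # SV does not fall
        ed = sweep.locus("LV", "ED")
        assert ed.shape == (3, 2)

    def test_run_study_healthy_outputs(self, tmp_path, config):
        """The orchestrator writes the metrics table, time series and
        manifest for the cases it runs."""
        import json
        from triseg.experiments import run_study
        report = run_study(config, cases=[], out_dir=str(tmp_path),
                           n_transient=12, n_record=1)
        df = report.metrics_frame()
        assert set(df["ventricle"]) == {"LV", "RV"}
        assert (tmp_path / "metrics.csv").exists()
        assert (tmp_path / "timeseries_Healthy.csv").exists()
        manifest = json.loads((tmp_path / "manifest.json").read_text())
        assert manifest["cases"][0]["label"] == "Healthy"
        assert manifest["calibration"]["gamma"] == pytest.approx(
            report.calibration["gamma"])


class TestSeptalCurvature:
    def test_phases_and_positivity(self, healthy_model):
        from triseg.circulation import simulate
        res = simulate(healthy_model, tbv=4600.0, n_transient=8, n_record=1)
        c = septal_curvature_timecourse(res)
        assert c.minimum > 0.0
        # the phase masks are disjoint
        assert not np.any(c.ejection & c.isovolumic_relaxation)
        assert not np.any(c.isovolumic_relaxation & c.filling)
        assert c.isovolumic_relaxation.any()
        assert np.isfinite(c.plateau)
        assert c.diastolic_min <= c.plateau
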