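"""Unit and property tests for the stabilometric index computations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from copstab import cop_metrics as cm
from copstab.synthetic_cohort import generate_trajectory

from conftest import make_recording


class TestPreprocess:
    def test_constant_signal_annihilated(self):
        rec = make_recording(ap=np.full(100, 5.0), ml=np.full(100, 5.0))
        s = cm.preprocess(rec)
        assert np.allclose(s.AP, 0) and np.allclose(s.ML, 0) and np.allclose(s.RD, 0)

    def test_mean_removal_and_resultant(self):
        rec = make_recording(ap=[0.0, 2.0], ml=[0.0, 0.0])
        s = cm.preprocess(rec)
        np.testing.assert_allclose(s.AP, [-1.0, 1.0])
        np.testing.assert_allclose(s.RD, [1.0, 1.0])

    def test_duration_convention(self):
        rec = make_recording(ap=np.zeros(3000), ml=np.zeros(3000))
        assert cm.preprocess(rec).T == pytest.approx(59.98)

    def test_too_short_rejected(self):
        with pytest.raises(cm.InvalidRecordingError):
            make_recording(ap=[1.0], ml=[1.0])

    def test_irregular_grid_rejected(self):
        t = np.array([0.0, 0.02, 0.05])
        with pytest.raises(cm.ResamplingRequiredError):
            cm.CoPRecording(subject_id="s", condition="OE", sample_rate=50.0,
                            t=t, ml=np.zeros(3), ap=np.zeros(3))


class TestResample:
    def test_uniform_input_is_identity(self):
        t = np.arange(50) / 50.0
        x = np.sin(t)
        t2, x2 = cm.resample(t, x, 50.0)
        np.testing.assert_allclose(t2, t)
        np.testing.assert_allclose(x2, x)

    def test_linear_midpoint(self):
        t2, x2 = cm.resample([0.0, 0.04], [0.0, 1.0], 50.0)
        np.testing.assert_allclose(t2, [0.0, 0.02, 0.04])
        np.testing.assert_allclose(x2, [0.0, 0.5, 1.0])

    def test_jittered_sine_recovery(self, rng):
        # oracle: the analytic sine evaluated on the uniform grid
        t = np.sort(rng.uniform(0, 10, 4000))
        t[0], t[-1] = 0.0, 10.0
        x = np.sin(2 * np.pi * 0.7 * t)
        t2, x2 = cm.resample(t, x, 50.0)
        rmse = np.sqrt(np.mean((x2 - np.sin(2 * np.pi * 0.7 * t2)) ** 2))
        assert rmse < 1e-3

    def test_duplicate_timestamps_rejected(self):
        with pytest.raises(ValueError):
            cm.resample([0.0, 0.1, 0.1], [0.0, 1.0, 2.0], 50.0)


class TestDistanceMeasures:
    def test_constant_signal_all_zero(self):
        s = cm.preprocess(make_recording(ap=np.full(10, 3.0), ml=np.full(10, 3.0)))
        dm = cm.distance_measures(s)
        for key in ("MDIST", "RDIST", "RANGE", "MVEL", "TOTEX"):
            assert dm[key] == 0.0

    def test_hand_summed_excursion(self):
        # AP = [0, 1, 0, -1, 0] at 50 Hz: total |excursion| 4 mm over 0.08 s
        s = cm.preprocess(make_recording(ap=[0.0, 1.0, 0.0, -1.0, 0.0],
                                         ml=np.zeros(5)))
        assert cm.distance_measures(s)["MVELAP"] == pytest.approx(4.0 / 0.08)

    def test_circular_sway_analytic_limit(self):
        # full circle, R = 5 mm, f = 0.5 Hz sampled at 50 Hz
        R, f, fs = 5.0, 0.5, 50.0
        t = np.arange(100) / fs
        rec = make_recording(ap=R * np.cos(2 * np.pi * f * t),
                             ml=R * np.sin(2 * np.pi * f * t))
        dm = cm.distance_measures(cm.preprocess(rec))
        assert dm["MDIST"] == pytest.approx(R, rel=1e-6)
        assert dm["MVEL"] == pytest.approx(2 * np.pi * R * f, rel=0.01)

    def test_planar_range_matches_brute_force(self, rng):
        ap, ml = rng.normal(size=200), rng.normal(size=200)
        s = cm.preprocess(make_recording(ap=ap, ml=ml))
        d2 = ((s.AP[:, None] - s.AP) ** 2 + (s.ML[:, None] - s.ML) ** 2)
        assert cm.distance_measures(s)["RANGE"] == pytest.approx(
            np.sqrt(d2.max()), rel=1e-12)

    def test_planar_velocity_dominates_axes(self, rng):
        s = cm.preprocess(make_recording(ap=rng.normal(size=300),
                                         ml=rng.normal(size=300)))
        dm = cm.distance_measures(s)
        assert dm["MVEL"] >= dm["MVELAP"]
        assert dm["MVEL"] >= dm["MVELML"]


class TestAreaMeasures:
    def test_confidence_ellipse_closed_form(self):
        # sample variance exactly 1 on both axes, covariance exactly 0
        ap = np.array([1.0, -1.0, 1.0, -1.0]) * math.sqrt(3.0 / 4.0)
        ml = np.array([1.0, 1.0, -1.0, -1.0]) * math.sqrt(3.0 / 4.0)
        s = cm.preprocess(make_recording(ap=ap, ml=ml))
        am = cm.area_measures(s)
        assert am["AREA_CE"] == pytest.approx(2 * math.pi * 3.00, rel=1e-12)

    def test_sway_area_shoelace_square(self):
        # unit-square loop traversed once in T = 1 s: area 4 mm^2 per 1 s
        ap = np.array([1.0, -1.0, -1.0, 1.0, 1.0])
        ml = np.array([1.0, 1.0, -1.0, -1.0, 1.0])
        rec = make_recording(ap=ap, ml=ml, rate=4.0)
        am = cm.area_measures(cm.preprocess(rec))
        assert am["AREA_SW"] == pytest.approx(4.0, rel=1e-12)

    def test_degenerate_input_gives_zeros(self):
        s = cm.preprocess(make_recording(ap=np.full(10, 2.0), ml=np.full(10, 2.0)))
        am = cm.area_measures(s)
        assert am["AREA_CC"] == am["AREA_CE"] == am["AREA_SW"] == 0.0


class TestHybridMeasures:
    def test_circular_sway_rotation_frequency(self):
        R, f, fs = 5.0, 0.5, 50.0
        t = np.arange(1000) / fs  # 10 full cycles
        rec = make_recording(ap=R * np.cos(2 * np.pi * f * t),
                             ml=R * np.sin(2 * np.pi * f * t))
        hm = cm.hybrid_measures(cm.preprocess(rec))
        assert hm["MFREQ"] == pytest.approx(f, rel=0.01)

    def test_constant_signal_zero_by_convention(self):
        s = cm.preprocess(make_recording(ap=np.full(10, 1.0), ml=np.full(10, 1.0)))
        hm = cm.hybrid_measures(s)
        assert hm["MFREQ"] == hm["MFREQAP"] == hm["MFREQML"] == 0.0

    def test_triangle_wave_against_brute_force(self):
        # MFREQAP must equal MVELAP / (4 sqrt(2) MDISTAP) computed directly,
        # and converge to sqrt(2) f for a triangle wave
        f, fs, n = 0.5, 50.0, 6000
        t = np.arange(n) / fs
        from scipy.signal import sawtooth
        ap = 3.0 * sawtooth(2 * np.pi * f * t, width=0.5)
        s = cm.preprocess(make_recording(ap=ap, ml=np.zeros(n)))
        dm = cm.distance_measures(s)
        hm = cm.hybrid_measures(s, dm)
        oracle = dm["MVELAP"] / (4 * math.sqrt(2) * dm["MDISTAP"])
        assert hm["MFREQAP"] == pytest.approx(oracle, rel=1e-12)
        assert hm["MFREQAP"] == pytest.approx(math.sqrt(2) * f, rel=0.02)

    def test_mfreq_identity_machine_precision(self, sway_recording):
        s = cm.preprocess(sway_recording)
        dm = cm.distance_measures(s)
        hm = cm.hybrid_measures(s, dm)
        assert hm["MFREQ"] * 2 * math.pi * dm["MDIST"] == pytest.approx(
            dm["MVEL"], rel=1e-12)


class TestFrequencyMeasures:
    def test_pure_tone_line_spectrum(self):
        fs, n = 50.0, 3001
        t = np.arange(n) / fs
        rec = make_recording(ap=2.0 * np.sin(2 * np.pi * 1.0 * t), ml=np.zeros(n))
        fm = cm.frequency_measures(cm.preprocess(rec))
        bin_width = 0.1  # 10 s Welch segments
        assert abs(fm["POWER50AP"] - 1.0) <= bin_width
        assert abs(fm["POWER95AP"] - 1.0) <= 2 * bin_width
        assert fm["CFREQAP"] == pytest.approx(1.0, abs=0.05)
        assert fm["FREQDAP"] < 0.1

    def test_white_noise_median_near_band_midpoint(self, rng):
        n = 30000
        rec = make_recording(ap=rng.normal(size=n), ml=np.zeros(n))
        fm = cm.frequency_measures(cm.preprocess(rec))
        assert fm["POWER50AP"] == pytest.approx((0.15 + 5.0) / 2, abs=0.3)

    def test_zero_signal_reports_zero(self):
        rec = make_recording(ap=np.zeros(600), ml=np.zeros(600))
        fm = cm.frequency_measures(cm.preprocess(rec))
        for key in ("POWERAP", "POWER50AP", "POWER95AP", "CFREQAP", "FREQDAP"):
            assert fm[key] == 0.0

    def test_short_record_single_segment_warning(self):
        rec = make_recording(ap=np.sin(np.arange(100)), ml=np.zeros(100))
        with pytest.warns(UserWarning, match="single segment"):
            cm.frequency_measures(cm.preprocess(rec))

    def test_ordering_and_bounds(self, sway_recording):
        fm = cm.frequency_measures(cm.preprocess(sway_recording))
        for axis in ("AP", "ML", "RD"):
            assert 0.15 <= fm[f"POWER50{axis}"] <= fm[f"POWER95{axis}"] <= 5.0
            assert fm[f"POWER{axis}"] >= 0.0
            assert 0.0 <= fm[f"FREQD{axis}"] <= 1.0


class TestMetricVector:
    def test_registry_has_39_names(self):
        assert len(cm.METRIC_NAMES) == 39
        assert len(set(cm.METRIC_NAMES)) == 39

    def test_subject_vector_has_78_entries(self, sway_recording):
        rec_ce = cm.CoPRecording(subject_id=sway_recording.subject_id, condition="CE",
                                 sample_rate=sway_recording.sample_rate,
                                 t=sway_recording.t, ml=sway_recording.ml,
                                 ap=sway_recording.ap)
        vec = cm.compute_all_metrics(sway_recording, rec_ce)
        assert len(vec) == 78
        # identical recordings in both conditions: OE values equal CE values
        for name in cm.METRIC_NAMES:
            assert vec[f"{name}OE"] == vec[f"{name}CE"]

    def test_missing_condition_marked_nan(self, sway_recording):
        vec = cm.compute_all_metrics(sway_recording, None)
        assert len(vec) == 78
        assert all(np.isnan(vec[f"{n}CE"]) for n in cm.METRIC_NAMES)
        assert all(np.isfinite(vec[f"{n}OE"]) for n in cm.METRIC_NAMES)

    def test_translation_invariance(self, sway_recording):
        base = cm.compute_metrics(sway_recording)
        shifted = make_recording(ap=sway_recording.ap + 123.4,
                                 ml=sway_recording.ml - 55.5)
        moved = cm.compute_metrics(shifted)
        for name in cm.METRIC_NAMES:
            assert moved[name] == pytest.approx(base[name], rel=1e-8, abs=1e-10)

    def test_scale_covariance(self, sway_recording):
        c = 2.0
        base = cm.compute_metrics(sway_recording)
        scaled = cm.compute_metrics(make_recording(ap=c * sway_recording.ap,
                                                   ml=c * sway_recording.ml))
        linear = [n for n in cm.METRIC_NAMES
                  if n.startswith(("MDIST", "RDIST", "RANGE", "TOTEX", "MVEL"))]
        quadratic = ["AREA_CC", "AREA_CE", "AREA_SW", "POWERAP", "POWERML", "POWERRD"]
        invariant = [n for n in cm.METRIC_NAMES
                     if n.startswith(("MFREQ", "CFREQ", "POWER50", "POWER95", "FREQD"))]
        for n in linear:
            assert scaled[n] == pytest.approx(c * base[n], rel=1e-9)
        for n in quadratic:
            assert scaled[n] == pytest.approx(c ** 2 * base[n], rel=1e-9)
        for n in invariant:
            assert scaled[n] == pytest.approx(base[n], rel=1e-9)

    def test_mixed_subjects_rejected(self, sway_recording):
        other = cm.CoPRecording(subject_id="someone-else", condition="CE",
                                sample_rate=50.0, t=np.arange(20) / 50.0,
                                ml=np.ones(20), ap=np.arange(20.0))
        with pytest.raises(ValueError, match="different subjects"):
            cm.compute_all_metrics(sway_recording, other)


class TestFileInterfaces:
    def test_recording_roundtrip(self, tmp_path, sway_recording):
        path = tmp_path / f"{sway_recording.subject_id}_OE.csv"
        cm.write_recording_csv(sway_recording, path)
        back = cm.read_recording_csv(path)
        assert back.subject_id == sway_recording.subject_id
        assert back.condition == "OE"
        np.testing.assert_allclose(back.ap, sway_recording.ap, atol=1e-4)

    def test_tidy_and_wide_outputs(self, sway_recording):
        vec = cm.compute_all_metrics(sway_recording, None)
        tidy = cm.metrics_to_tidy("s1", vec)
        assert len(tidy) == 78
        assert set(tidy.columns) == {"subject_id", "metric", "value", "units"}
        wide = cm.metrics_to_wide({"s1": vec})
        assert wide.shape == (1, 78)


@settings(deadline=None, max_examples=30)
@given(data=st.data())
def test_sway_series_invariants(data):
    """Zero mean, non-negative RD, and RD <= |AP| + |ML| on arbitrary input."""
    n = data.draw(st.integers(min_value=2, max_value=200))
    vals = st.floats(min_value=-100, max_value=100, allow_nan=False)
    ap = np.array(data.draw(st.lists(vals, min_size=n, max_size=n)))
    ml = np.array(data.draw(st.lists(vals, min_size=n, max_size=n)))
    s = cm.preprocess(make_recording(ap=ap, ml=ml))
    assert abs(s.AP.mean()) < 1e-9 and abs(s.ML.mean()) < 1e-9
    assert (s.RD >= 0).all()
    assert (s.RD <= np.abs(s.AP) + np.abs(s.ML) + 1e-12).all()
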