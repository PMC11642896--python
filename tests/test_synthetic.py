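"""Generator behaviour: breath construction, RR calibration, cohort
reproducibility and demographic structure."""

import numpy as np
import pytest

from cardioresp import (
    CARDIAC,
    DEFAULT_PRESETS,
    HEALTHY,
    SPORT,
    Recording,
    generate_cohort,
    generate_recording,
    generate_respiration,
    generate_rri,
)
from cardioresp.preprocess import bandpass_resp
from cardioresp.respiratory import detect_breaths, respiratory_features
from cardioresp.synthetic import CalibrationError, calibrate_preset


class TestRespiration:
    def test_exact_breath_count_without_jitter(self):
        """15 breaths/min with zero rate spread over 5 min -> 75 cycles."""
        p = HEALTHY.with_(resprate_mean=15.0, resprate_sd=0.0, ie_ratio=1.0)
        w = generate_respiration(p, 300.0, 250.0, seed=0)
        breaths = detect_breaths(bandpass_resp(w, 250.0), 250.0)
        assert len(breaths) == 75

    def test_symmetric_waveform_has_unit_ie_ratio(self):
        p = HEALTHY.with_(resprate_sd=0.0, ie_ratio=1.0, amplitude_jitter=0.0)
        w = generate_respiration(p, 300.0, 250.0, seed=0)
        feats = respiratory_features(detect_breaths(w, 250.0))
        assert feats["IERatio_Mean"] == pytest.approx(1.0, abs=0.02)

    def test_waveform_zero_mean_and_in_band(self):
        w = generate_respiration(SPORT, 300.0, 250.0, seed=3)
        assert abs(w.mean()) < 1e-9
        freqs = np.fft.rfftfreq(len(w), 1 / 250.0)
        power = np.abs(np.fft.rfft(w)) ** 2
        in_band = (freqs >= 0.05) & (freqs <= 0.67)
        assert power[in_band].sum() / power.sum() > 0.9

    @pytest.mark.parametrize(
        "kwargs", [dict(duration_s=-1.0), dict(fs=-5.0), dict(subject_rate=50.0)]
    )
    def test_rejects_invalid_arguments(self, kwargs):
        with pytest.raises(ValueError):
            generate_respiration(HEALTHY, **{"duration_s": 300.0, "fs": 250.0,
                                             "seed": 0, **kwargs})


class TestCalibration:
    def test_zero_coupling_gives_zero_respiratory_scale(self):
        cal = calibrate_preset(HEALTHY.with_(coupling_strength=0.0), seed=1)
        assert cal.g == 0.0
        assert cal.a > 0.0

    def test_full_coupling_gives_zero_intrinsic_scale(self):
        cal = calibrate_preset(HEALTHY.with_(coupling_strength=1.0), seed=1)
        assert cal.a == 0.0
        assert cal.g > 0.0

    def test_cardiac_pilot_rmssd_within_five_percent(self):
        """Monte-Carlo pilot reproduces the 55.3 ms group target."""
        cal = calibrate_preset(CARDIAC, seed=12345)
        assert 52.5 <= cal.achieved_rmssd <= 58.1
        assert abs(cal.achieved_share - CARDIAC.coupling_strength) <= 0.05

    def test_determinism_given_seed(self):
        a = calibrate_preset(SPORT.with_(ar_phi=0.75), n_pilot=100, seed=5)
        b = calibrate_preset(SPORT.with_(ar_phi=0.75), n_pilot=100, seed=5)
        assert (a.a, a.g) == (b.a, b.g)


class TestRri:
    def test_all_intervals_positive_and_cover_duration(self, healthy_recording):
        rri = healthy_recording.rri
        assert np.all(rri > 0)
        assert rri.sum() / 1000.0 >= 300.0 - 2.0  # last beat may overshoot

    def test_uncoupled_rri_independent_of_respiration(self, healthy_cal):
        """With coupling 0 the same respiration yields identical RRi."""
        p0 = HEALTHY.with_(coupling_strength=0.0)
        cal = calibrate_preset(p0, seed=1)
        w1 = generate_respiration(p0, 300.0, 250.0, seed=10)
        w2 = generate_respiration(p0, 300.0, 250.0, seed=11)
        r1 = generate_rri(p0, w1, 250.0, seed=42, scales=(cal.a, cal.g))
        r2 = generate_rri(p0, w2, 250.0, seed=42, scales=(cal.a, cal.g))
        n = min(len(r1), len(r2))
        assert np.allclose(r1[:n], r2[:n])

    def test_negative_scales_rejected(self):
        w = generate_respiration(HEALTHY, 300.0, 250.0, seed=0)
        with pytest.raises(CalibrationError):
            generate_rri(HEALTHY, w, 250.0, seed=0, scales=(-1.0, 1.0))

    def test_empty_respiration_rejected(self):
        with pytest.raises(ValueError):
            generate_rri(HEALTHY, np.empty(0), 250.0, seed=0)


class TestCohort:
    def test_study_size_composition(self):
        recs = generate_cohort(n_per_group=(2, 3, 4), seed=0)
        assert len(recs) == 9
        labels = [r.group_label for r in recs]
        assert labels.count("Cardiac") == 2
        assert labels.count("Healthy") == 3
        assert labels.count("Sport") == 4

    def test_byte_level_determinism(self):
        a = generate_cohort(n_per_group=(1, 1, 1), seed=123)
        b = generate_cohort(n_per_group=(1, 1, 1), seed=123)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.resp, rb.resp)
            assert np.array_equal(ra.rri, rb.rri)
            assert ra.demographics == rb.demographics

    def test_sport_group_is_all_male(self):
        recs = generate_cohort(n_per_group=(1, 1, 12), seed=7)
        sport = [r for r in recs if r.group_label == "Sport"]
        assert all(r.demographics["sex"] == "M" for r in sport)

    def test_bmi_consistent_with_height_weight(self):
        recs = generate_cohort(n_per_group=(2, 2, 2), seed=3)
        for r in recs:
            d = r.demographics
            assert d["bmi"] == pytest.approx(
                d["weight_kg"] / (d["height_cm"] / 100.0) ** 2, abs=1e-6
            )

    def test_rejects_empty_group(self):
        with pytest.raises(ValueError):
            generate_cohort(n_per_group=(0, 1, 1), seed=0)


class TestRecordingInvariants:
    def test_short_recording_rejected(self):
        with pytest.raises(ValueError):
            Recording(
                resp=np.zeros(100), rri=np.full(10, 800.0), fs=250.0,
                demographics={"age": 12, "sex": "M", "height_cm": 150,
                              "weight_kg": 45, "bmi": 20.0},
                group_label="Healthy",
            )

    def test_inconsistent_bmi_rejected(self, healthy_recording):
        demo = dict(healthy_recording.demographics)
        demo["bmi"] = demo["bmi"] + 1.0
        with pytest.raises(ValueError):
            Recording(
                resp=healthy_recording.resp, rri=healthy_recording.rri,
                fs=250.0, demographics=demo, group_label="Healthy",
            )
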