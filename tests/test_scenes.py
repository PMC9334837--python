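"""Synthetic scene generator: determinism, headroom, truth recovery."""

import numpy as np
import pytest

from ultrasurvey.band_metrics import Band, band_level
from ultrasurvey.calibration import (CalibratedRecording, apply_calibration,
                                     fit_calibration, spl_rms)
from ultrasurvey.scenes import (BackgroundSegment, HeadroomError, SceneSpec,
                                SourceSpec, apply_enclosure,
                                render_paired_devices, render_scene,
                                scene_from_dict)
from ultrasurvey.spectral import autospectrum
from ultrasurvey.wav_io import read_wav, write_wav

RATE = 250_000.0


def _basic_spec(seed=1, **kw):
    defaults = dict(
        duration_s=4.0,
        background=(BackgroundSegment(20_000.0, 60_000.0, 40.0),),
        sources=(
            SourceSpec(kind="cal_tone", t_start_s=0.0, t_end_s=2.0,
                       f_lo_hz=1000.0, label="cal"),
            SourceSpec(kind="narrowband", t_start_s=2.0, t_end_s=4.0,
                       f_lo_hz=30_000.0, f_hi_hz=35_000.0,
                       level_db_spl=55.0, label="nb"),
        ),
        seed=seed,
    )
    defaults.update(kw)
    return SceneSpec(**defaults)


def _calibrated(rec, truth):
    return CalibratedRecording(
        pressure_pa=rec.samples / truth["sensitivity_counts_per_pa"],
        rate_hz=rec.rate_hz)


class TestRenderScene:
    def test_same_seed_bit_identical_wav(self, tmp_path):
        spec = _basic_spec(seed=42)
        rec1, _ = render_scene(spec)
        rec2, _ = render_scene(spec)
        np.testing.assert_array_equal(rec1.samples, rec2.samples)
        p1 = write_wav(rec1, tmp_path / "a.wav")
        p2 = write_wav(rec2, tmp_path / "b.wav")
        assert open(p1, "rb").read() == open(p2, "rb").read()

    def test_different_seed_differs(self):
        rec1, _ = render_scene(_basic_spec(seed=1))
        rec2, _ = render_scene(_basic_spec(seed=2))
        assert not np.array_equal(rec1.samples, rec2.samples)

    def test_clipping_names_offending_source(self):
        spec = _basic_spec(sources=(
            SourceSpec(kind="beep", t_start_s=1.0, t_end_s=2.0,
                       f_lo_hz=5000.0, level_db_spl=150.0, label="siren"),))
        with pytest.raises(HeadroomError, match="siren"):
            render_scene(spec)

    def test_cal_tone_truth_recovered_within_tenth_db(self):
        for seed in range(1, 6):
            rec, truth = render_scene(_basic_spec(seed=seed))
            model = fit_calibration(rec, (0.0, 2.0))
            cal = apply_calibration(rec, model)
            assert spl_rms(cal, (0.5, 1.5)) == pytest.approx(94.0, abs=0.1)

    def test_narrowband_truth_recovered_within_half_db(self):
        band = Band("nb", 30_000.0, 35_000.0)
        for seed in range(1, 6):
            rec, truth = render_scene(_basic_spec(seed=seed))
            cal = _calibrated(rec, truth)
            sp = autospectrum(cal, epoch_start_s=3.0)
            expected = next(
                s["expected_measured_in_band_db_spl"] for s in truth["sources"]
                if s["label"] == "nb")
            assert band_level(sp, band) == pytest.approx(expected, abs=0.5)

    def test_energy_additivity_of_disjoint_sources(self):
        one = SceneSpec(
            duration_s=3.0,
            sources=(SourceSpec(kind="narrowband", t_start_s=0.0, t_end_s=3.0,
                                f_lo_hz=30_000.0, f_hi_hz=40_000.0,
                                level_db_spl=60.0),),
            seed=3)
        two = SceneSpec(
            duration_s=3.0,
            sources=one.sources + (
                SourceSpec(kind="narrowband", t_start_s=0.0, t_end_s=3.0,
                           f_lo_hz=60_000.0, f_hi_hz=70_000.0,
                           level_db_spl=60.0),),
            seed=3)
        rec1, t1 = render_scene(one)
        rec2, t2 = render_scene(two)
        l1 = spl_rms(_calibrated(rec1, t1))
        l2 = spl_rms(_calibrated(rec2, t2))
        assert l2 - l1 == pytest.approx(3.01, abs=0.2)

    def test_seed_is_mandatory(self):
        with pytest.raises(ValueError):
            SceneSpec(duration_s=4.0)

    def test_too_short_scene_rejected(self):
        with pytest.raises(ValueError):
            SceneSpec(duration_s=1.0, seed=1)

    def test_source_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError):
            SceneSpec(duration_s=4.0, seed=1, sources=(
                SourceSpec(kind="narrowband", t_start_s=0, t_end_s=1,
                           f_lo_hz=120_000.0, f_hi_hz=130_000.0),))

    def test_wav_round_trip_within_one_lsb(self, tmp_path):
        rec, _ = render_scene(_basic_spec(seed=9))
        back = read_wav(write_wav(rec, tmp_path / "scene.wav"))
        assert np.max(np.abs(back.samples - rec.samples)) <= 2.0**-15


class TestEnclosure:
    def test_zero_attenuation_is_identity(self):
        x = np.random.default_rng(0).normal(size=10_000)
        np.testing.assert_allclose(apply_enclosure(x, RATE, None), x)
        np.testing.assert_allclose(apply_enclosure(x, RATE, 0.0), x)

    def test_flat_attenuation_scales_level(self):
        x = np.random.default_rng(0).normal(size=10_000)
        y = apply_enclosure(x, RATE, 10.0)
        assert 20 * np.log10(np.std(x) / np.std(y)) == pytest.approx(10.0)

    def test_banded_attenuation_hits_only_its_band(self):
        rng = np.random.default_rng(1)
        from ultrasurvey.scenes import _band_noise
        n = int(RATE)
        x = _band_noise(rng, n, RATE, 10_000, 20_000) + \
            _band_noise(rng, n, RATE, 40_000, 50_000)
        y = apply_enclosure(x, RATE, [(40_000.0, 50_000.0, 20.0)])
        cal_x = CalibratedRecording(pressure_pa=x, rate_hz=RATE)
        cal_y = CalibratedRecording(pressure_pa=y, rate_hz=RATE)
        low = Band("low", 10_000, 20_000)
        high = Band("high", 40_000, 50_000)
        sx, sy = autospectrum(cal_x), autospectrum(cal_y)
        assert band_level(sx, low) - band_level(sy, low) == \
            pytest.approx(0.0, abs=0.05)
        assert band_level(sx, high) - band_level(sy, high) == \
            pytest.approx(20.0, abs=0.1)

    def test_negative_attenuation_rejected(self):
        with pytest.raises(ValueError):
            apply_enclosure(np.zeros(100), RATE, -3.0)


class TestPairedDevices:
    def test_rf_only_content_absent_from_reference_device(self):
        spec = _basic_spec(sources=_basic_spec().sources + (
            SourceSpec(kind="fm_burst", t_start_s=2.5, t_end_s=3.0,
                       f_lo_hz=48_000.0, f_hi_hz=50_000.0,
                       level_db_spl=55.0, rf_only=True, label="rf"),))
        rec_a, rec_b, truth = render_paired_devices(spec)
        assert not np.array_equal(rec_a.samples, rec_b.samples)
        # device B truth reports the rf source as absent
        b_rf = next(s for s in truth["device_b_sources"] if s["label"] == "rf")
        assert b_rf["on_device"] is False

    def test_without_artifact_devices_are_identical(self):
        rec_a, rec_b, truth = render_paired_devices(_basic_spec(seed=5))
        np.testing.assert_array_equal(rec_a.samples, rec_b.samples)

    def test_reference_device_must_be_rf_immune(self):
        with pytest.raises(ValueError):
            render_paired_devices(_basic_spec(rf_susceptible=False))


class TestSceneSerialization:
    def test_scene_from_dict_round_trip(self):
        payload = {
            "duration_s": 4.0,
            "rate_hz": 250_000.0,
            "seed": 7,
            "background": [
                {"f_lo_hz": 20_000.0, "f_hi_hz": 60_000.0,
                 "level_db_spl": 40.0}],
            "sources": [
                {"kind": "cal_tone", "t_start_s": 0.0, "t_end_s": 2.0,
                 "f_lo_hz": 1000.0}],
        }
        spec = scene_from_dict(payload)
        rec, truth = render_scene(spec)
        assert truth["seed"] == 7
        assert rec.duration_s == 4.0
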