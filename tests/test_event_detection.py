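"""Event detection and RF-artifact screening on the canonical scenes."""

import numpy as np
import pytest

from ultrasurvey import FineSpectrogram, apply_calibration, fit_calibration, \
    fine_spectrogram
from ultrasurvey.band_metrics import Band, STANDARD_BANDS
from ultrasurvey.event_detection import (DetectionEvent, barrier_plausibility,
                                         detect_fm, detect_impact,
                                         detect_tonal, fit_background,
                                         rf_screen)
from ultrasurvey.fixtures import lights_scene
from ultrasurvey.spectral import Spectrogram

BIN_HZ = 15.625
FINE_BIN_HZ = 200.0


def _fine_analysis(wk, which):
    rec = wk[f"recording_{which}"]
    cal = apply_calibration(rec, fit_calibration(rec, wk["cal_window_s"]))
    fine = fine_spectrogram(cal)
    keep = fine.times_s >= wk["cal_window_s"][1]
    fine = FineSpectrogram(times_s=fine.times_s[keep],
                           bin_freqs_hz=fine.bin_freqs_hz,
                           levels_db_spl=fine.levels_db_spl[keep],
                           frame_seconds=fine.frame_seconds)
    lo, hi = wk["background_window_s"]
    bg = fit_background(
        fine, [i for i, t in enumerate(fine.times_s) if lo <= t < hi])
    return fine, bg


class TestFitBackground:
    def test_recovers_configured_spectrum(self, lights):
        bg = lights["background_model"]
        for seg in lights["truth"]["background"]:
            band = Band("seg", seg["f_lo_hz"], seg["f_hi_hz"])
            assert bg.band_level(band) == pytest.approx(
                seg["level_db_spl"], abs=0.5)

    def test_median_robust_to_one_contaminated_epoch(self, lights):
        spg = lights["analysis_spectrogram"]
        clean = fit_background(spg, range(5))
        levels = spg.level_matrix().copy()
        levels[2] += 30.0  # contaminate one designated background epoch
        contaminated = fit_background(_Matrix(levels, spg), range(5))
        # the contamination is +30 dB; the median moves at most one order
        # statistic, so band readings stay within a fraction of a decibel
        for band in STANDARD_BANDS:
            assert contaminated.band_level(band) == pytest.approx(
                clean.band_level(band), abs=0.5)

    def test_too_few_background_epochs_rejected(self, lights):
        with pytest.raises(ValueError):
            fit_background(lights["spectrogram"], [1, 2])


class _Matrix:
    """Minimal spectrogram stand-in wrapping a prepared level matrix."""

    def __init__(self, levels, spg):
        self._levels = levels
        self.bin_freqs_hz = spg.bin_freqs_hz
        self.times_s = spg.times_s

    def level_matrix(self):
        return self._levels


class TestDetectTonal:
    def test_lights_scene_yields_one_event_with_correct_extent(self, lights):
        events = detect_tonal(lights["analysis_spectrogram"],
                              lights["background_model"])
        assert len(events) == 1
        ev = events[0]
        assert ev.kind == "tonal"
        f_lo, f_hi = lights["delta_band_hz"]
        assert ev.f_lo_hz == pytest.approx(f_lo, abs=2 * BIN_HZ)
        assert ev.f_hi_hz == pytest.approx(f_hi, abs=2 * BIN_HZ)
        assert ev.t_start_s == pytest.approx(12.0, abs=1.0)
        assert ev.t_end_s == pytest.approx(22.0, abs=1.0)
        assert ev.excess_db >= 3.0

    def test_attenuated_lights_undetectable(self, lights_inside_ivc):
        events = detect_tonal(lights_inside_ivc["analysis_spectrogram"],
                              lights_inside_ivc["background_model"])
        assert events == []

    def test_no_false_positives_on_pure_background(self):
        """Background-only epochs: well under one detection per 100 epochs."""
        n_events = n_epochs = 0
        for seed in (211, 212, 213, 214):
            fx = lights_scene(seed=seed)
            spec = fx["spec"]
            from ultrasurvey.scenes import SceneSpec, render_scene
            quiet = SceneSpec(
                duration_s=spec.duration_s, rate_hz=spec.rate_hz,
                background=spec.background,
                sources=(spec.sources[0],),  # calibration tone only
                full_scale_pa=spec.full_scale_pa, seed=seed)
            from tests_helpers import analyse_scene
            spg, bg, sub = analyse_scene(quiet)
            n_events += len(detect_tonal(sub, bg))
            n_events += len(detect_impact(sub, bg))
            n_epochs += len(sub.epochs)
        assert n_epochs >= 90
        assert n_events <= 1

    def test_detection_monotone_in_source_level(self):
        """Raising the source level never removes its event."""
        from ultrasurvey.scenes import SceneSpec, SourceSpec, render_scene
        from tests_helpers import analyse_scene
        for boost in (0.0, 6.0, 12.0):
            fx = lights_scene(seed=77)
            spec = fx["spec"]
            src = spec.sources[1]
            louder = SourceSpec(kind=src.kind, t_start_s=src.t_start_s,
                                t_end_s=src.t_end_s, f_lo_hz=src.f_lo_hz,
                                f_hi_hz=src.f_hi_hz,
                                level_db_spl=src.level_db_spl + boost,
                                label=src.label)
            scene = SceneSpec(duration_s=spec.duration_s,
                              rate_hz=spec.rate_hz,
                              background=spec.background,
                              sources=(spec.sources[0], louder),
                              full_scale_pa=spec.full_scale_pa, seed=77)
            spg, bg, sub = analyse_scene(
                scene, background_epochs=fx["off_epochs"])
            events = detect_tonal(sub, bg)
            assert len(events) >= 1, f"event lost at +{boost} dB"


class TestDetectImpact:
    def test_metal_impact_detected_with_published_ultrasonic_excess(
            self, forceps_metal):
        events = detect_impact(forceps_metal["analysis_spectrogram"],
                               forceps_metal["background_model"])
        assert len(events) == 1
        ev = events[0]
        assert ev.kind == "impact"
        assert ev.t_start_s <= 4.2 < ev.t_end_s
        assert ev.band_excess_db["Ultrasonic"] == pytest.approx(49.34, abs=1.0)
        assert ev.band_excess_db["Mouse peak"] == pytest.approx(53.88, abs=1.0)

    def test_neoprene_impact_excess(self, forceps_neoprene):
        events = detect_impact(forceps_neoprene["analysis_spectrogram"],
                               forceps_neoprene["background_model"])
        assert len(events) == 1
        assert events[0].band_excess_db["Ultrasonic"] == pytest.approx(
            13.27, abs=1.0)

    def test_impact_still_detected_inside_ivc(self, forceps_inside_ivc):
        events = detect_impact(forceps_inside_ivc["analysis_spectrogram"],
                               forceps_inside_ivc["background_model"])
        assert len(events) == 1

    def test_tonal_only_scene_has_no_impact_events(self, lights):
        events = detect_impact(lights["analysis_spectrogram"],
                               lights["background_model"])
        assert events == []


class TestDetectFM:
    def test_walkie_components_and_beep(self, walkie_paired):
        fine, bg = _fine_analysis(walkie_paired, "a")
        events = detect_fm(fine, bg)
        fm = [e for e in events if e.kind == "fm"]
        tonal = [e for e in events if e.kind == "tonal"]
        n_bursts = len(walkie_paired["burst_times_s"])
        assert len(fm) == 2 * n_bursts
        for lo, hi in walkie_paired["fm_bands_hz"]:
            matching = [e for e in fm
                        if abs(e.f_lo_hz - lo) <= 2 * FINE_BIN_HZ
                        and abs(e.f_hi_hz - hi) <= 2 * FINE_BIN_HZ]
            assert len(matching) == n_bursts, (lo, hi)
        # the steady audible beep is tonal, not fm
        assert len(tonal) == n_bursts
        assert all(abs(0.5 * (e.f_lo_hz + e.f_hi_hz)
                       - walkie_paired["beep_freq_hz"]) < 500 for e in tonal)
        # simultaneous components share a group id
        for t0 in walkie_paired["burst_times_s"]:
            ids = {e.group_id for e in events
                   if abs(e.t_start_s - t0) < 0.2}
            assert len(ids) == 1

    def test_reference_device_sees_only_the_beep(self, walkie_paired):
        fine, bg = _fine_analysis(walkie_paired, "b")
        events = detect_fm(fine, bg)
        assert all(e.kind == "tonal" for e in events)
        assert all(e.f_hi_hz < 20_000 for e in events)

    def test_background_only_frames_are_empty(self, walkie_paired):
        fine, bg = _fine_analysis(walkie_paired, "b")
        lo, hi = walkie_paired["background_window_s"]
        keep = (fine.times_s >= lo) & (fine.times_s < hi)
        quiet = FineSpectrogram(times_s=fine.times_s[keep],
                                bin_freqs_hz=fine.bin_freqs_hz,
                                levels_db_spl=fine.levels_db_spl[keep],
                                frame_seconds=fine.frame_seconds)
        assert detect_fm(quiet, bg) == []


class TestRFScreen:
    def test_walkie_flags_exactly_the_ultrasonic_components(
            self, walkie_paired):
        fine_a, bg_a = _fine_analysis(walkie_paired, "a")
        fine_b, bg_b = _fine_analysis(walkie_paired, "b")
        ev_a = detect_fm(fine_a, bg_a)
        ev_b = detect_fm(fine_b, bg_b)
        flagged = rf_screen(ev_a, ev_b, bg_b=bg_b)
        rf = [e for e in flagged if "suspected_rf" in e.flags]
        assert {e.kind for e in rf} == {"fm"}
        assert all(e.is_ultrasonic for e in rf)
        assert len(rf) == 2 * len(walkie_paired["burst_times_s"])
        beeps = [e for e in flagged if e.f_lo_hz < 20_000]
        assert all("suspected_rf" not in e.flags for e in beeps)

    def test_concordant_detections_unflagged(self, walkie_paired):
        fine_a, bg_a = _fine_analysis(walkie_paired, "a")
        ev_a = detect_fm(fine_a, bg_a)
        flagged = rf_screen(ev_a, ev_a)
        assert all("suspected_rf" not in e.flags for e in flagged)

    def test_event_missing_because_reference_floor_too_high(self):
        ev = DetectionEvent(kind="fm", t_start_s=1.0, t_end_s=1.5,
                            f_lo_hz=48_000, f_hi_hz=50_000,
                            peak_level_db_spl=55.0, excess_db=20.0)
        # reference background sitting at 50 dB per bin: event would be
        # invisible to B, so its absence is not evidence of RF pickup
        freqs = np.arange(0, 125_001, 200.0)
        from ultrasurvey.event_detection import BackgroundModel
        loud_floor = BackgroundModel(bin_freqs_hz=freqs,
                                     median_db_spl=np.full(freqs.size, 50.0),
                                     spread_db=np.ones(freqs.size))
        flagged = rf_screen([ev], [], bg_b=loud_floor)
        assert flagged[0].flags == frozenset()
        quiet_floor = BackgroundModel(bin_freqs_hz=freqs,
                                      median_db_spl=np.full(freqs.size, 0.0),
                                      spread_db=np.ones(freqs.size))
        flagged = rf_screen([ev], [], bg_b=quiet_floor)
        assert "suspected_rf" in flagged[0].flags

    def test_time_shift_of_both_devices_leaves_flags_unchanged(self):
        def shift(e, dt):
            from dataclasses import replace
            return replace(e, t_start_s=e.t_start_s + dt,
                           t_end_s=e.t_end_s + dt)
        ev_a = [DetectionEvent(kind="fm", t_start_s=1.0, t_end_s=1.5,
                               f_lo_hz=48_000, f_hi_hz=50_000,
                               peak_level_db_spl=55.0, excess_db=20.0)]
        ev_b = [DetectionEvent(kind="tonal", t_start_s=1.0, t_end_s=1.5,
                               f_lo_hz=2_900, f_hi_hz=3_100,
                               peak_level_db_spl=70.0, excess_db=30.0)]
        base = rf_screen(ev_a, ev_b)
        moved = rf_screen([shift(e, 5.0) for e in ev_a],
                          [shift(e, 5.0) for e in ev_b])
        assert [e.flags for e in base] == [e.flags for e in moved]

    def test_disjoint_coverage_rejected(self):
        with pytest.raises(ValueError):
            rf_screen([], [], coverage_a=(0.0, 10.0), coverage_b=(20.0, 30.0))


class TestBarrierPlausibility:
    def test_undiminished_inside_level_flags_through_barrier(self):
        outside = DetectionEvent(kind="fm", t_start_s=0, t_end_s=1,
                                 f_lo_hz=48_000, f_hi_hz=50_000,
                                 peak_level_db_spl=55.0, excess_db=20.0)
        inside = DetectionEvent(kind="fm", t_start_s=0, t_end_s=1,
                                f_lo_hz=48_000, f_hi_hz=50_000,
                                peak_level_db_spl=54.8, excess_db=20.0)
        flags = barrier_plausibility(outside, inside,
                                     expected_attenuation_db=10.0)
        assert flags == {"through_barrier", "inside_ivc_audible"}

    def test_expected_attenuation_means_audible_but_plausible(self):
        outside = DetectionEvent(kind="impact", t_start_s=0, t_end_s=1,
                                 f_lo_hz=4, f_hi_hz=100_000,
                                 peak_level_db_spl=112.11, excess_db=26.15)
        inside = DetectionEvent(kind="impact", t_start_s=0, t_end_s=1,
                                f_lo_hz=4, f_hi_hz=100_000,
                                peak_level_db_spl=112.11 - 9.81,
                                excess_db=36.9)
        flags = barrier_plausibility(outside, inside,
                                     expected_attenuation_db=10.0)
        assert flags == {"inside_ivc_audible"}

    def test_absent_inside_event_no_flags(self):
        outside = DetectionEvent(kind="tonal", t_start_s=0, t_end_s=1,
                                 f_lo_hz=40_300, f_hi_hz=47_400,
                                 peak_level_db_spl=33.1, excess_db=4.1)
        assert barrier_plausibility(outside, None) == frozenset()
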