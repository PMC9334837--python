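"""Canonical synthetic scenes for the three survey investigations.

Each builder returns the rendered recording, its sidecar truth, and the
epoch bookkeeping a survey of that scene needs (calibration window,
background epochs, event epochs).  Levels come from the published survey
readings in :mod:`ultrasurvey.survey_data`; everything else (durations,
timings) is fixture convention, chosen so each scene fits in a few seconds
of audio while leaving at least three clean background epochs.

Band-partition shaping: the published readings are levels in four
overlapping standard bands.  They are converted to energies on the disjoint
partition 4-20 Hz / 20 Hz-10 kHz / 10-20 kHz / 20-100 kHz by energy
subtraction; a negative remainder (possible at printed precision) is
clamped to zero.  Impact components are shaped to the energy *difference*
between the measured and background rows, so the measured epoch —
background plus transient — reproduces the measured row.
"""

from __future__ import annotations

import numpy as np

from .band_metrics import energy_sum_db
from .calibration import REF_LEVEL_DB_SPL
from .scenes import BackgroundSegment, SceneSpec, SourceSpec, render_scene, \
    render_paired_devices
from . import survey_data as sd

__all__ = [
    "band_partition",
    "impact_partition",
    "CAL_WINDOW_S",
    "lights_scene",
    "forceps_scene",
    "walkie_talkie_paired_scene",
]

#: Calibration-tone window shared by all fixtures (pistonphone segment).
CAL_WINDOW_S = (0.0, 2.0)

#: Guard gap left below every internal partition edge (40 analysis bins at
#: 15.625 Hz).  A loud segment ending exactly on a shared band edge leaks
#: into the analyser bins just above the edge — which the half-open band
#: convention assigns to the quieter neighbouring band: the Welch window's
#: near-lobe skirt of a 100+ dB SPL transient ending at 10 kHz spans some
#: 600 Hz and would bias the quiet mouse-peak band by whole decibels.  The
#: gap removes < 0.03 dB of segment energy.
EDGE_GUARD_HZ = 40 * 15.625

_PARTITION_EDGES = ((4.0, 20.0), (20.0, 10_000.0), (10_000.0, 20_000.0),
                    (20_000.0, 100_000.0))


def _e(level_db: float) -> float:
    return 10.0 ** (level_db / 10.0)


def _db(energy: float) -> float:
    return 10.0 * np.log10(energy) if energy > 0 else float("-inf")


def band_partition(levels: dict) -> list[tuple[float, float, float]]:
    """Convert standard-band levels to disjoint partition-segment levels.

    Expects keys Total / Human audible / Mouse peak / Ultrasonic.  Returns
    ``(f_lo, f_hi, level_db)`` with empty (non-positive-energy) segments
    dropped.
    """
    e_total = _e(levels["Total"])
    e_human = _e(levels["Human audible"])
    e_mouse = _e(levels["Mouse peak"])
    e_ultra = _e(levels["Ultrasonic"])
    seg_energies = (
        max(e_total - e_human - e_ultra, 0.0),  # 4-20 Hz remainder
        max(e_human - e_mouse, 0.0),            # 20 Hz - 10 kHz
        e_mouse,                                # 10 - 20 kHz
        e_ultra,                                # 20 - 100 kHz
    )
    return [(lo, hi, _db(en))
            for (lo, hi), en in zip(_PARTITION_EDGES, seg_energies)
            if en > 0.0]


def impact_partition(background: dict, measured: dict) -> list[tuple[float, float, float]]:
    """Partition-segment levels of the transient alone (measured minus background)."""
    bg = {(lo, hi): lvl for lo, hi, lvl in band_partition(background)}
    out = []
    for lo, hi, meas in band_partition(measured):
        e_diff = _e(meas) - _e(bg.get((lo, hi), float("-inf"))) \
            if (lo, hi) in bg else _e(meas)
        if e_diff > 0:
            out.append((lo, hi, _db(e_diff)))
    return out


def _guard_edges(segs: list[tuple[float, float, float]],
                 gap_hz: float = EDGE_GUARD_HZ) -> list[tuple[float, float, float]]:
    """Shrink segment upper edges that touch the next segment's lower edge."""
    out = []
    for i, (lo, hi, lvl) in enumerate(segs):
        touches_next = any(abs(nlo - hi) < 1e-9 for nlo, _, _ in segs[i + 1:])
        shrink = touches_next and (hi - gap_hz) > lo + gap_hz
        out.append((lo, hi - gap_hz if shrink else hi, lvl))
    return out


def _cal_source() -> SourceSpec:
    return SourceSpec(kind="cal_tone", t_start_s=CAL_WINDOW_S[0],
                      t_end_s=CAL_WINDOW_S[1], f_lo_hz=1000.0,
                      level_db_spl=REF_LEVEL_DB_SPL, label="pistonphone")


def lights_scene(seed: int, source_attenuation_db: float = 0.0) -> dict:
    """Fluorescent-light emission scene: 40.3-47.4 kHz band-limited noise.

    The background is shaped so the delta band reads the published off-level
    (29.0 dB SPL); the light source adds the energy difference so lights-on
    epochs read the published 33.1 dB SPL.  ``source_attenuation_db``
    emulates measuring from inside an enclosure (the source attenuates, the
    at-microphone ambient does not).
    """
    f_lo, f_hi = sd.LIGHTS_DELTA_BAND_HZ
    ultra_bw = 100_000.0 - 20_000.0
    # flat ultrasonic background whose delta-band share is the off-level
    ultra_level = sd.LIGHTS_OFF_DB + 10.0 * np.log10(ultra_bw / (f_hi - f_lo))
    source_level = _db(_e(sd.LIGHTS_ON_DB) - _e(sd.LIGHTS_OFF_DB))
    on_interval = (12.0, 22.0)
    bg_segments = _guard_edges([
        (20.0, 10_000.0, 55.0),
        (10_000.0, 20_000.0, 44.0),
        (20_000.0, 100_000.0, ultra_level),
    ])
    spec = SceneSpec(
        duration_s=26.0,
        background=tuple(BackgroundSegment(*s) for s in bg_segments),
        sources=(
            _cal_source(),
            SourceSpec(kind="narrowband", t_start_s=on_interval[0],
                       t_end_s=on_interval[1], f_lo_hz=f_lo, f_hi_hz=f_hi,
                       level_db_spl=source_level, label="ceiling lights"),
        ),
        enclosure_attenuation_db=(
            source_attenuation_db if source_attenuation_db else None),
        full_scale_pa=4.0,
        seed=seed,
        label="lights scene",
    )
    rec, truth = render_scene(spec)
    return {
        "recording": rec,
        "truth": truth,
        "spec": spec,
        "cal_window_s": CAL_WINDOW_S,
        "delta_band_hz": (f_lo, f_hi),
        "on_epochs": list(range(12, 22)),
        "off_epochs": list(range(2, 12)) + list(range(22, 26)),
        "expected_on_db": energy_sum_db(
            [sd.LIGHTS_OFF_DB, source_level - source_attenuation_db]),
        "expected_off_db": sd.LIGHTS_OFF_DB,
    }


_CONDITION_ROWS = {
    "metal": (sd.FORCEPS_METAL_BG, sd.FORCEPS_METAL_MEASURED),
    "neoprene": (sd.FORCEPS_NEOPRENE_BG, sd.FORCEPS_NEOPRENE_MEASURED),
}


def forceps_scene(seed: int, condition: str = "metal",
                  enclosure_db: float = 0.0) -> dict:
    """Forceps-drop scene shaped to a published background/measured row pair.

    The transient lands in epoch 4; epochs 2-3 and 5-7 are clean background.
    ``enclosure_db`` > 0 renders the inside-IVC variant (flat attenuation of
    the airborne transient).
    """
    if condition not in _CONDITION_ROWS:
        raise ValueError(f"condition must be one of {sorted(_CONDITION_ROWS)}")
    bg_row, meas_row = _CONDITION_ROWS[condition]
    onset = 4.2
    impact_sources = tuple(
        SourceSpec(kind="impact", t_start_s=onset, t_end_s=onset + 0.6,
                   f_lo_hz=lo, f_hi_hz=hi, level_db_spl=lvl, decay_s=0.06,
                   label=f"forceps {lo:g}-{hi:g} Hz")
        for lo, hi, lvl in _guard_edges(impact_partition(bg_row, meas_row))
    )
    spec = SceneSpec(
        duration_s=8.0,
        background=tuple(BackgroundSegment(lo, hi, lvl)
                         for lo, hi, lvl in _guard_edges(band_partition(bg_row))),
        sources=(_cal_source(),) + impact_sources,
        enclosure_attenuation_db=enclosure_db if enclosure_db else None,
        full_scale_pa=250.0,
        seed=seed,
        label=f"forceps scene ({condition})",
    )
    rec, truth = render_scene(spec)
    return {
        "recording": rec,
        "truth": truth,
        "spec": spec,
        "cal_window_s": CAL_WINDOW_S,
        "impact_epoch": 4,
        "background_epochs": [2, 3, 5, 6, 7],
        "background_row": dict(bg_row),
        "measured_row": {
            k: energy_sum_db([bg_row[k],
                              _attenuated_component(bg_row, meas_row, k,
                                                    enclosure_db)])
            for k in meas_row
        },
    }


def _attenuated_component(bg_row: dict, meas_row: dict, band: str,
                          enclosure_db: float) -> float:
    comp = _db(max(_e(meas_row[band]) - _e(bg_row[band]), 0.0))
    return comp - enclosure_db


def walkie_talkie_paired_scene(seed: int, n_bursts: int = 3,
                               fm_level_db: float = 55.0,
                               beep_level_db: float = 70.0,
                               include_artifact: bool = True) -> dict:
    """Paired-device walkie-talkie scene.

    Each button press produces an acoustic beep (3 kHz) plus — on the
    RF-susceptible device only — two swept ultrasonic FM components
    (48-50 kHz and 98-102 kHz) injected as electromagnetic pickup.
    """
    burst_times = [3.0 + 2.0 * k for k in range(n_bursts)]
    burst_len = 0.4
    sources: list[SourceSpec] = [_cal_source()]
    for t0 in burst_times:
        if include_artifact:
            sources.append(SourceSpec(
                kind="fm_burst", t_start_s=t0, t_end_s=t0 + burst_len,
                f_lo_hz=48_000.0, f_hi_hz=50_000.0, level_db_spl=fm_level_db,
                rf_only=True, label="rf component 48-50 kHz"))
            sources.append(SourceSpec(
                kind="fm_burst", t_start_s=t0, t_end_s=t0 + burst_len,
                f_lo_hz=98_000.0, f_hi_hz=102_000.0, level_db_spl=fm_level_db,
                rf_only=True, label="rf component 98-102 kHz"))
        sources.append(SourceSpec(
            kind="beep", t_start_s=t0, t_end_s=t0 + burst_len,
            f_lo_hz=3_000.0, level_db_spl=beep_level_db, label="beep"))
    spec = SceneSpec(
        duration_s=3.0 + 2.0 * n_bursts,
        background=(
            BackgroundSegment(20.0, 10_000.0, 50.0),
            BackgroundSegment(10_000.0, 20_000.0, 40.0),
            BackgroundSegment(20_000.0, 120_000.0, 40.0),
        ),
        sources=tuple(sources),
        rf_susceptible=True,
        full_scale_pa=4.0,
        seed=seed,
        label="walkie-talkie paired scene",
    )
    rec_a, rec_b, truth = render_paired_devices(spec)
    return {
        "recording_a": rec_a,
        "recording_b": rec_b,
        "truth": truth,
        "spec": spec,
        "cal_window_s": CAL_WINDOW_S,
        "burst_times_s": burst_times,
        "burst_len_s": burst_len,
        "background_window_s": (2.0, 3.0),
        "fm_bands_hz": [(48_000.0, 50_000.0), (98_000.0, 102_000.0)],
        "beep_freq_hz": 3_000.0,
    }
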