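"""Detection and classification of ultrasonic events, with RF-artifact screening.

Three event shapes cover the survey's noise sources:

* **tonal** — continuous narrowband emission (fluorescent ceiling lights):
  a contiguous time-frequency region of 1 s epochs whose bins sit above the
  background by a persistent margin, no wider than ~10 kHz.
* **impact** — broadband transients (metal-on-metal drops): epochs whose
  super-threshold bins span tens of kilohertz, lasting at most two epochs.
* **fm** — frequency-modulated bursts (walkie-talkie interference): ridges
  tracked on a short-frame spectrogram whose center frequency moves by at
  least 1 kHz within the event.

Detection thresholds differ by view because their level statistics differ:
epoch spectra are Welch averages of ~30 segments (per-bin standard deviation
well under 1 dB), so a 3 dB excess — a doubling of sound pressure — is a
dependable margin for persistent tonal detection; single 5 ms frames are
unaveraged periodograms whose bins fluctuate by several dB, so ridge
detection uses a 12 dB excess plus a persistence requirement.

RF screening implements the cross-device argument: an ultrasonic event seen
by an RF-susceptible microphone but absent from an RF-immune reference that
*could* have detected it is flagged ``suspected_rf``; an ultrasonic event
detected inside an enclosure at a level the enclosure's attenuation cannot
explain is flagged ``through_barrier`` (sound is readily absorbed and does
not pass through walls undiminished — electromagnetic pickup does).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .band_metrics import Band, STANDARD_BANDS, band_level, energy_sum_db

__all__ = [
    "DetectionEvent",
    "BackgroundModel",
    "fit_background",
    "detect_tonal",
    "detect_impact",
    "detect_fm",
    "rf_screen",
    "barrier_plausibility",
    "events_to_records",
]

AUDIBLE_LIMIT_HZ = 20_000.0


@dataclass(frozen=True)
class DetectionEvent:
    kind: str  # "tonal" | "impact" | "fm"
    t_start_s: float
    t_end_s: float
    f_lo_hz: float
    f_hi_hz: float
    peak_level_db_spl: float
    excess_db: float
    flags: frozenset = frozenset()
    group_id: int | None = None
    band_excess_db: dict | None = None

    def __post_init__(self) -> None:
        if not (self.t_start_s < self.t_end_s):
            raise ValueError("event needs t_start < t_end")
        if not (self.f_lo_hz < self.f_hi_hz):
            raise ValueError("event needs f_lo < f_hi")

    @property
    def is_ultrasonic(self) -> bool:
        return self.f_lo_hz >= AUDIBLE_LIMIT_HZ

    def with_flags(self, *new_flags: str) -> "DetectionEvent":
        return replace(self, flags=self.flags | frozenset(new_flags))


@dataclass(frozen=True)
class BackgroundModel:
    """Per-bin robust background spectrum: median level and MAD-based spread."""

    bin_freqs_hz: np.ndarray
    median_db_spl: np.ndarray
    spread_db: np.ndarray

    # duck-type as a spectrum for band_level()
    @property
    def bin_levels_db_spl(self) -> np.ndarray:
        return self.median_db_spl

    def band_level(self, band: Band) -> float:
        return band_level(self, band)


def fit_background(spec, background_epochs: Iterable[int]) -> BackgroundModel:
    """Robust per-bin background from designated background epochs/frames.

    ``spec`` is a Spectrogram or FineSpectrogram; at least three background
    rows are required.  The median is insensitive to a contaminated epoch.
    """
    idx = np.asarray(sorted(set(int(i) for i in background_epochs)), dtype=int)
    if idx.size < 3:
        raise ValueError(
            f"need >= 3 background epochs, got {idx.size}"
        )
    levels = spec.level_matrix()[idx]
    median = np.median(levels, axis=0)
    mad = np.median(np.abs(levels - median), axis=0)
    return BackgroundModel(
        bin_freqs_hz=np.asarray(spec.bin_freqs_hz, dtype=float),
        median_db_spl=median,
        spread_db=1.4826 * mad,
    )


def _smooth_energy(levels_db: np.ndarray, width: int) -> np.ndarray:
    """Moving energy average along the frequency axis (odd width)."""
    if width <= 1:
        return levels_db
    power = 10.0 ** (levels_db / 10.0)
    kernel = np.ones(width) / width
    smoothed = np.apply_along_axis(
        lambda row: np.convolve(row, kernel, mode="same"), -1, power)
    with np.errstate(divide="ignore"):
        return 10.0 * np.log10(smoothed)


def _clusters(mask_row: np.ndarray, gap_bins: int) -> list[tuple[int, int]]:
    """Contiguous super-threshold runs, merging gaps of <= gap_bins; inclusive."""
    hits = np.flatnonzero(mask_row)
    if hits.size == 0:
        return []
    out = []
    start = prev = hits[0]
    for k in hits[1:]:
        if k - prev <= gap_bins + 1:
            prev = k
        else:
            out.append((start, prev))
            start = prev = k
    out.append((start, prev))
    return out


def _extent_level(level_rows: np.ndarray, freqs: np.ndarray,
                  f_lo: float, f_hi: float) -> float:
    sel = (freqs >= f_lo) & (freqs <= f_hi)
    return max(energy_sum_db(row[sel]) for row in np.atleast_2d(level_rows))


def detect_tonal(spec, bg: BackgroundModel, min_excess_db: float = 3.0,
                 min_duration_s: float = 3.0, max_bandwidth_hz: float = 10_000.0,
                 gap_bins: int = 2, gap_epochs: int = 1,
                 smooth_bins: int = 3) -> list[DetectionEvent]:
    """Continuous narrowband events on the 1 s epoch spectrogram.

    A light 3-bin energy smoothing is applied before thresholding so that a
    band-limited source sitting a few dB over background is found as one
    contiguous region rather than a comb of noisy bins; the super-threshold
    mask is then morphologically closed (bridging gaps of up to ``gap_bins``
    bins and ``gap_epochs`` epochs) and connected regions become candidate
    events, kept when they persist for ``min_duration_s`` and stay narrower
    than ``max_bandwidth_hz``.
    """
    from scipy import ndimage

    if min_excess_db <= 0 or min_duration_s <= 0:
        raise ValueError("thresholds must be positive")
    freqs = np.asarray(spec.bin_freqs_hz, dtype=float)
    raw_levels = spec.level_matrix()
    levels = _smooth_energy(raw_levels, smooth_bins)
    bg_sm = _smooth_energy(bg.median_db_spl[None, :], smooth_bins)[0]
    mask = levels >= bg_sm + min_excess_db

    closed = ndimage.binary_closing(
        mask, structure=np.ones((2 * gap_epochs + 1, 2 * gap_bins + 1)))
    closed &= ndimage.binary_dilation(
        mask, structure=np.ones((1, 2 * gap_bins + 1)))
    labels, n_regions = ndimage.label(closed, structure=np.ones((3, 3)))

    epoch_len = 1.0
    if getattr(spec, "epochs", None):
        epoch_len = float(spec.epochs[0].epoch_seconds)
    min_epochs = int(np.ceil(min_duration_s / epoch_len))
    times = np.asarray(spec.times_s, dtype=float)
    dt = float(times[1] - times[0]) if times.size > 1 else epoch_len

    bin_w = float(freqs[1] - freqs[0])
    events: list[DetectionEvent] = []
    for region in ndimage.find_objects(labels, n_regions):
        t_sl, f_sl = region
        n_epochs = t_sl.stop - t_sl.start
        if n_epochs < min_epochs:
            continue
        # the energy smoothing spreads any real source over >= smooth_bins
        # bins; narrower regions are isolated noise excursions
        if f_sl.stop - f_sl.start < smooth_bins:
            continue
        if freqs[f_sl.stop - 1] - freqs[f_sl.start] > max_bandwidth_hz:
            continue
        rows = raw_levels[t_sl, f_sl]
        peak = max(energy_sum_db(r) for r in rows)
        bg_lvl = energy_sum_db(bg.median_db_spl[f_sl])
        events.append(DetectionEvent(
            kind="tonal",
            t_start_s=float(times[t_sl.start]),
            t_end_s=float(times[t_sl.stop - 1]) + dt,
            f_lo_hz=float(freqs[f_sl.start]),
            f_hi_hz=float(freqs[f_sl.stop - 1]) + bin_w,
            peak_level_db_spl=peak,
            excess_db=peak - bg_lvl,
        ))
    return events


def detect_impact(spec, bg: BackgroundModel, min_excess_db: float = 10.0,
                  min_bandwidth_hz: float = 50_000.0,
                  max_epochs: int = 2) -> list[DetectionEvent]:
    """Broadband transient events: wide super-threshold spans, <= 2 epochs."""
    if min_excess_db <= 0 or min_bandwidth_hz <= 0:
        raise ValueError("thresholds must be positive")
    freqs = np.asarray(spec.bin_freqs_hz, dtype=float)
    levels = spec.level_matrix()
    mask = levels >= bg.median_db_spl + min_excess_db
    times = np.asarray(spec.times_s, dtype=float)
    dt = float(times[1] - times[0]) if times.size > 1 else 1.0

    candidate = np.zeros(len(levels), dtype=bool)
    spans = []
    for i, row in enumerate(mask):
        hits = np.flatnonzero(row)
        if hits.size and freqs[hits[-1]] - freqs[hits[0]] >= min_bandwidth_hz:
            candidate[i] = True
            spans.append((hits[0], hits[-1]))
        else:
            spans.append(None)

    events: list[DetectionEvent] = []
    i = 0
    while i < candidate.size:
        if not candidate[i]:
            i += 1
            continue
        j = i
        while j + 1 < candidate.size and candidate[j + 1]:
            j += 1
        if j - i + 1 <= max_epochs:
            lo = min(spans[k][0] for k in range(i, j + 1))
            hi = max(spans[k][1] for k in range(i, j + 1))
            f_lo, f_hi = float(freqs[lo]), float(freqs[hi])
            rows = levels[i: j + 1]
            sel = slice(lo, hi + 1)
            peak = max(energy_sum_db(r[sel]) for r in rows)
            bg_lvl = energy_sum_db(bg.median_db_spl[sel])
            band_excess = {}
            for band in STANDARD_BANDS:
                bsel = (freqs >= max(band.f_lo_hz, 4.0)) & (freqs < band.f_hi_hz)
                if not np.any(bsel):
                    continue
                meas = max(energy_sum_db(r[bsel]) for r in rows)
                band_excess[band.name] = meas - energy_sum_db(
                    bg.median_db_spl[bsel])
            events.append(DetectionEvent(
                kind="impact",
                t_start_s=float(times[i]),
                t_end_s=float(times[j]) + dt,
                f_lo_hz=f_lo, f_hi_hz=f_hi,
                peak_level_db_spl=peak,
                excess_db=peak - bg_lvl,
                band_excess_db=band_excess,
            ))
        i = j + 1
    return events


def detect_fm(fine, bg: BackgroundModel, min_excess_db: float = 12.0,
              min_frames: int = 5, fm_min_range_hz: float = 1000.0,
              link_tol_hz: float = 2000.0, gap_bins: int = 2,
              max_dropout_frames: int = 2) -> list[DetectionEvent]:
    """Ridge-tracked narrowband components on a fine-frame spectrogram.

    A ridge whose center frequency moves by >= 1 kHz within the event is
    ``fm``; a steady ridge is ``tonal``.  Simultaneous components are
    separate events sharing a ``group_id``.
    """
    if fine.frame_seconds > 0.010:
        raise ValueError("frame length must be <= 10 ms to resolve modulation")
    freqs = np.asarray(fine.bin_freqs_hz, dtype=float)
    levels = fine.level_matrix()
    mask = levels >= bg.median_db_spl + min_excess_db
    times = np.asarray(fine.times_s, dtype=float)
    dt = float(times[1] - times[0]) if times.size > 1 else fine.frame_seconds

    ridges: list[dict] = []
    active: list[dict] = []
    for t_idx in range(len(levels) + 1):
        clusters = []
        if t_idx < len(levels):
            for lo, hi in _clusters(mask[t_idx], gap_bins):
                sel = slice(lo, hi + 1)
                p = 10.0 ** (levels[t_idx, sel] / 10.0)
                center = float(np.sum(freqs[sel] * p) / np.sum(p))
                clusters.append({"lo": lo, "hi": hi, "center": center,
                                 "level": energy_sum_db(levels[t_idx, sel])})
        still = []
        used = set()
        for tr in active:
            best, best_d = None, None
            for j, cl in enumerate(clusters):
                if j in used:
                    continue
                d = abs(cl["center"] - tr["centers"][-1])
                if d <= link_tol_hz and (best_d is None or d < best_d):
                    best, best_d = j, d
            if best is not None:
                used.add(best)
                cl = clusters[best]
                tr["centers"].append(cl["center"])
                tr["lo"] = min(tr["lo"], cl["lo"])
                tr["hi"] = max(tr["hi"], cl["hi"])
                tr["peak"] = max(tr["peak"], cl["level"])
                tr["end"] = t_idx
                tr["miss"] = 0
                still.append(tr)
            else:
                tr["miss"] += 1
                if tr["miss"] <= max_dropout_frames and t_idx < len(levels):
                    still.append(tr)
                else:
                    ridges.append(tr)
        for j, cl in enumerate(clusters):
            if j not in used:
                still.append({"start": t_idx, "end": t_idx, "miss": 0,
                              "centers": [cl["center"]],
                              "lo": cl["lo"], "hi": cl["hi"],
                              "peak": cl["level"]})
        active = still
    ridges.extend(active)

    events: list[DetectionEvent] = []
    for tr in ridges:
        n = tr["end"] - tr["start"] + 1
        if n < min_frames:
            continue
        f_range = max(tr["centers"]) - min(tr["centers"])
        kind = "fm" if f_range >= fm_min_range_hz else "tonal"
        sel = slice(tr["lo"], tr["hi"] + 1)
        bg_lvl = energy_sum_db(bg.median_db_spl[sel])
        # extent is the ridge-center range (the modulation span), at least
        # one bin wide for steady tones
        bin_w = float(freqs[1] - freqs[0])
        f_lo = float(min(tr["centers"]))
        f_hi = max(float(max(tr["centers"])), f_lo + bin_w)
        events.append(DetectionEvent(
            kind=kind,
            t_start_s=float(times[tr["start"]]),
            t_end_s=float(times[tr["end"]]) + dt,
            f_lo_hz=f_lo,
            f_hi_hz=f_hi,
            peak_level_db_spl=tr["peak"],
            excess_db=tr["peak"] - bg_lvl,
        ))

    # simultaneous events share a group id
    events.sort(key=lambda e: e.t_start_s)
    grouped: list[DetectionEvent] = []
    group_id = -1
    group_end = -np.inf
    for ev in events:
        if ev.t_start_s > group_end:
            group_id += 1
            group_end = ev.t_end_s
        else:
            group_end = max(group_end, ev.t_end_s)
        grouped.append(replace(ev, group_id=group_id))
    return grouped


def _overlaps(ev_a: DetectionEvent, ev_b: DetectionEvent,
              time_tol_s: float) -> bool:
    time_ok = (ev_a.t_start_s - time_tol_s) < ev_b.t_end_s and \
              (ev_a.t_end_s + time_tol_s) > ev_b.t_start_s
    freq_ok = ev_a.f_lo_hz < ev_b.f_hi_hz and ev_a.f_hi_hz > ev_b.f_lo_hz
    return time_ok and freq_ok


def rf_screen(events_a: Sequence[DetectionEvent],
              events_b: Sequence[DetectionEvent],
              time_tol_s: float = 0.1,
              bg_b: BackgroundModel | None = None,
              device_offset_db: float = 0.0,
              b_min_excess_db: float = 12.0,
              coverage_a: tuple[float, float] | None = None,
              coverage_b: tuple[float, float] | None = None,
              ) -> list[DetectionEvent]:
    """Flag ultrasonic events on device A absent from reference device B.

    An ultrasonic event with no time/frequency-overlapping counterpart in B
    is flagged ``suspected_rf`` — but only when B could plausibly have
    detected it: the level expected at B (A's peak minus the configured
    device offset) must clear B's background in the event band by B's
    detection threshold.  Audible-band events (below 20 kHz) are exempt.
    """
    if coverage_a is not None and coverage_b is not None:
        if coverage_a[1] <= coverage_b[0] or coverage_b[1] <= coverage_a[0]:
            raise ValueError("device recordings do not cover a common interval")
    out = []
    for ev in events_a:
        if not ev.is_ultrasonic:
            out.append(ev)
            continue
        if any(_overlaps(ev, eb, time_tol_s) for eb in events_b):
            out.append(ev)
            continue
        detectable = True
        if bg_b is not None:
            expected_b = ev.peak_level_db_spl - device_offset_db
            floor_b = band_level(bg_b, Band("event", ev.f_lo_hz, ev.f_hi_hz))
            detectable = expected_b >= floor_b + b_min_excess_db
        out.append(ev.with_flags("suspected_rf") if detectable else ev)
    return out


def barrier_plausibility(event_outside: DetectionEvent,
                         event_inside: DetectionEvent | None,
                         expected_attenuation_db: float = 10.0,
                         margin_db: float = 3.0) -> frozenset:
    """Physical-plausibility flags for an event measured across an enclosure.

    If the event is detected inside at all, ``inside_ivc_audible`` is set.
    If its inside level is no more than ``expected_attenuation - margin`` dB
    below the outside level, the propagation is implausibly lossless and
    ``through_barrier`` is set — supporting an RF-artifact interpretation
    for ultrasonic content.
    """
    if event_inside is None:
        return frozenset()
    flags = {"inside_ivc_audible"}
    if event_inside.peak_level_db_spl >= (
        event_outside.peak_level_db_spl - (expected_attenuation_db - margin_db)
    ):
        flags.add("through_barrier")
    return frozenset(flags)


def events_to_records(events: Sequence[DetectionEvent]) -> list[dict]:
    """Plain-dict export (CSV/JSON rows) of detection events."""
    return [{
        "kind": e.kind,
        "t_start_s": e.t_start_s,
        "t_end_s": e.t_end_s,
        "f_lo_hz": e.f_lo_hz,
        "f_hi_hz": e.f_hi_hz,
        "peak_level_db_spl": e.peak_level_db_spl,
        "excess_db": e.excess_db,
        "group_id": e.group_id,
        "flags": ";".join(sorted(e.flags)),
    } for e in events]
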