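"""Seeded synthetic acoustic scenes emulating facility noise-survey conditions.

Every pipeline stage is testable without facility access: scenes are rendered
as calibrated pressure waveforms containing a 94 dB SPL / 1 kHz reference
tone, stationary piecewise-flat background noise with per-band targets,
continuous narrowband sources (fluorescent-light emission), exponentially
decaying broadband impact transients shaped to per-band epoch levels
(metal-on-metal forceps drops), swept-sinusoid FM bursts with an audible
beep (walkie-talkie operation and its radio-frequency pickup), and an
optional enclosure that attenuates airborne sources.

Conventions and physical simplifications:

* The stationary background is the ambient at the microphone position, so an
  enclosure attenuates *sources* but not the background (moving the
  microphone inside a cage changes which ambient it sits in; the fixture
  keeps the configured background as that ambient).
* The calibration tone emulates a pistonphone coupler sealed over the
  microphone: the background is muted during the tone window and the tone
  bypasses the enclosure.
* RF-only components are electromagnetic pickup, not sound: they bypass the
  enclosure entirely and appear only on RF-susceptible devices.
* Band-limited noise components are synthesized in the FFT domain (exactly
  band-limited) and energy-normalized to their targets, so rendered in-band
  levels are exact rather than realizations with sampling variance.

The rendered count stream maps pressure to normalized counts through
``counts = pressure * 10**(gain_db/20) / full_scale_pa``; a sample reaching
the 16-bit rail raises a headroom error naming the offending source.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .calibration import P_REF_PA, ref_pressure_rms_pa, REF_LEVEL_DB_SPL
from .band_metrics import energy_sum_db
from .wav_io import RawRecording

__all__ = [
    "BackgroundSegment",
    "SourceSpec",
    "SceneSpec",
    "HeadroomError",
    "render_scene",
    "render_paired_devices",
    "apply_enclosure",
    "scene_from_dict",
]

TRUTH_SCHEMA_VERSION = 1

SOURCE_KINDS = ("cal_tone", "narrowband", "impact", "fm_burst", "beep")


class HeadroomError(ValueError):
    """A source drives the rendered count stream onto the 16-bit rail."""


def _level_to_mean_square(level_db_spl: float) -> float:
    """Mean-square pressure (Pa^2) of a band at the given SPL."""
    return (P_REF_PA * 10.0 ** (level_db_spl / 20.0)) ** 2


@dataclass(frozen=True)
class BackgroundSegment:
    """A piecewise-flat background band: flat spectral density over [lo, hi)."""

    f_lo_hz: float
    f_hi_hz: float
    level_db_spl: float  # in-band SPL of this segment

    def __post_init__(self) -> None:
        if not (0 <= self.f_lo_hz < self.f_hi_hz):
            raise ValueError("background segment needs 0 <= f_lo < f_hi")


@dataclass(frozen=True)
class SourceSpec:
    """One scene source.

    ``level_db_spl`` is the in-band SPL over the active interval for
    continuous kinds, and the in-band level of the one-second epoch
    containing the onset for ``impact``.  ``fm_burst`` sweeps a sinusoid
    from ``f_lo_hz`` to ``f_hi_hz`` over the burst; ``beep`` and
    ``cal_tone`` are steady tones at ``f_lo_hz``.  ``rf_only`` marks
    electromagnetic pickup injected after all acoustic transforms.
    """

    kind: str
    t_start_s: float
    t_end_s: float
    f_lo_hz: float
    f_hi_hz: float = 0.0
    level_db_spl: float = REF_LEVEL_DB_SPL
    decay_s: float = 0.06
    rf_only: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in SOURCE_KINDS:
            raise ValueError(f"unknown source kind {self.kind!r}")
        if not (self.t_start_s < self.t_end_s):
            raise ValueError("source needs t_start < t_end")
        if self.kind in ("narrowband", "impact", "fm_burst") and not (
            0 < self.f_lo_hz < self.f_hi_hz
        ):
            raise ValueError(f"{self.kind} source needs 0 < f_lo < f_hi")


@dataclass(frozen=True)
class SceneSpec:
    duration_s: float
    rate_hz: float = 250_000.0
    background: tuple[BackgroundSegment, ...] = ()
    sources: tuple[SourceSpec, ...] = ()
    enclosure_attenuation_db: object = None  # None | float | [(lo, hi, dB), ...]
    gain_db: float = 0.0
    rf_susceptible: bool = True
    full_scale_pa: float = 4.0
    seed: int | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory for reproducible scenes")
        if self.duration_s < 2.0:
            raise ValueError("scenes must be at least 2 s long")
        nyq = self.rate_hz / 2.0
        for src in self.sources:
            if max(src.f_lo_hz, src.f_hi_hz) >= nyq:
                raise ValueError(
                    f"source {src.kind} extends beyond Nyquist {nyq} Hz"
                )
        object.__setattr__(self, "background", tuple(self.background))
        object.__setattr__(self, "sources", tuple(self.sources))

    @property
    def sensitivity_counts_per_pa(self) -> float:
        return 10.0 ** (self.gain_db / 20.0) / self.full_scale_pa


def _band_noise(rng: np.random.Generator, n: int, rate_hz: float,
                f_lo: float, f_hi: float) -> np.ndarray:
    """Unit-scale Gaussian noise exactly band-limited to [f_lo, f_hi)."""
    freqs = np.fft.rfftfreq(n, d=1.0 / rate_hz)
    mask = (freqs >= f_lo) & (freqs < f_hi)
    spec = np.zeros(freqs.size, dtype=complex)
    k = int(mask.sum())
    if k == 0:
        raise ValueError(f"band [{f_lo}, {f_hi}) Hz holds no FFT bins at n={n}")
    spec[mask] = rng.standard_normal(k) + 1j * rng.standard_normal(k)
    return np.fft.irfft(spec, n)


def _normalize_ms(x: np.ndarray, region: slice, target_ms: float) -> np.ndarray:
    """Scale x so its mean square over ``region`` equals ``target_ms`` exactly."""
    ms = float(np.mean(x[region] ** 2))
    if ms == 0.0:
        raise ValueError("cannot normalize an all-zero component")
    return x * np.sqrt(target_ms / ms)


def _sample_slice(t0: float, t1: float, rate: float, n: int) -> slice:
    return slice(max(int(round(t0 * rate)), 0), min(int(round(t1 * rate)), n))


def _enclosure_gain(attenuation, freqs: np.ndarray) -> np.ndarray:
    gain = np.ones(freqs.size)
    if attenuation is None:
        return gain
    if np.isscalar(attenuation):
        return gain * 10.0 ** (-float(attenuation) / 20.0)
    for f_lo, f_hi, att_db in attenuation:
        if att_db < 0:
            raise ValueError("enclosure attenuation must be >= 0 dB")
        mask = (freqs >= f_lo) & (freqs < f_hi)
        gain[mask] = 10.0 ** (-att_db / 20.0)
    return gain


def apply_enclosure(samples: np.ndarray, rate_hz: float, attenuation) -> np.ndarray:
    """Attenuate acoustic content per band via FFT-domain gain shaping.

    ``attenuation`` is a flat dB value or a list of ``(f_lo, f_hi, dB)``
    bands; ``None``/0 dB is the identity.
    """
    if attenuation is None:
        return samples.copy()
    if np.isscalar(attenuation):
        if attenuation < 0:
            raise ValueError("enclosure attenuation must be >= 0 dB")
        return samples * 10.0 ** (-float(attenuation) / 20.0)
    freqs = np.fft.rfftfreq(samples.size, d=1.0 / rate_hz)
    spec = np.fft.rfft(samples) * _enclosure_gain(attenuation, freqs)
    return np.fft.irfft(spec, samples.size)


def _attenuation_in_band(attenuation, f_lo: float, f_hi: float) -> float:
    """Representative attenuation (dB) of a source band under the enclosure."""
    if attenuation is None:
        return 0.0
    if np.isscalar(attenuation):
        return float(attenuation)
    mid = 0.5 * (f_lo + f_hi)
    for lo, hi, att in attenuation:
        if lo <= mid < hi:
            return float(att)
    return 0.0


def _background_level_in(background, f_lo: float, f_hi: float) -> float:
    """Background in-band SPL over [f_lo, f_hi) from piecewise-flat segments."""
    energies = []
    for seg in background:
        ov = max(0.0, min(f_hi, seg.f_hi_hz) - max(f_lo, seg.f_lo_hz))
        if ov > 0:
            frac = ov / (seg.f_hi_hz - seg.f_lo_hz)
            energies.append(seg.level_db_spl + 10.0 * np.log10(frac))
    return energy_sum_db(energies) if energies else float("-inf")


def _render_source(src: SourceSpec, spec: SceneSpec,
                   rng: np.random.Generator, n: int) -> np.ndarray:
    rate = spec.rate_hz
    out = np.zeros(n)
    window = _sample_slice(src.t_start_s, src.t_end_s, rate, n)
    n_win = window.stop - window.start
    t = np.arange(n_win) / rate
    if src.kind == "cal_tone":
        amp = np.sqrt(2.0) * ref_pressure_rms_pa(src.level_db_spl)
        out[window] = amp * np.sin(2 * np.pi * src.f_lo_hz * t)
    elif src.kind in ("narrowband",):
        noise = _band_noise(rng, n_win, rate, src.f_lo_hz, src.f_hi_hz)
        out[window] = _normalize_ms(noise, slice(None),
                                    _level_to_mean_square(src.level_db_spl))
    elif src.kind == "impact":
        # broadband transient: band noise, crest-limited, exponential decay,
        # normalized to the in-band level of the epoch containing the onset.
        # The crest limit bounds the peak so shaped transients cannot hit the
        # 16-bit rail; re-bandlimiting afterwards confines the (tiny, ~-40 dB)
        # clipping distortion to the source band, where the source masks it.
        noise = _band_noise(rng, n_win, rate, src.f_lo_hz, src.f_hi_hz)
        sigma = float(np.std(noise))
        noise = np.clip(noise, -3.3 * sigma, 3.3 * sigma)
        shaped = noise * np.exp(-t / src.decay_s)
        # re-bandlimit after crest limiting and enveloping: both the clipping
        # distortion and the onset-step sidebands would otherwise spill a
        # 1/f^2 skirt into quiet neighbouring bands
        freqs_w = np.fft.rfftfreq(n_win, d=1.0 / rate)
        band_mask = (freqs_w >= src.f_lo_hz) & (freqs_w < src.f_hi_hz)
        shaped = np.fft.irfft(np.fft.rfft(shaped) * band_mask, n_win)
        # 5 ms raised-cosine edge tapers: an abrupt window edge would radiate
        # a truncation skirt whose level rides on the random edge samples and
        # can swamp quiet neighbouring bands
        n_ramp = min(int(round(0.005 * rate)), n_win // 4)
        if n_ramp > 1:
            ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
            shaped[:n_ramp] *= ramp
            shaped[-n_ramp:] *= ramp[::-1]
        out[window] = shaped
        epoch0 = float(np.floor(src.t_start_s))
        epoch = _sample_slice(epoch0, epoch0 + 1.0, rate, n)
        out = _normalize_ms(out, epoch, _level_to_mean_square(src.level_db_spl))
    elif src.kind == "fm_burst":
        # linear sweep f_lo -> f_hi across the burst
        sweep_rate = (src.f_hi_hz - src.f_lo_hz) / (src.t_end_s - src.t_start_s)
        phase = 2 * np.pi * (src.f_lo_hz * t + 0.5 * sweep_rate * t**2)
        amp = np.sqrt(2.0) * P_REF_PA * 10.0 ** (src.level_db_spl / 20.0)
        out[window] = amp * np.sin(phase)
    elif src.kind == "beep":
        amp = np.sqrt(2.0) * P_REF_PA * 10.0 ** (src.level_db_spl / 20.0)
        out[window] = amp * np.sin(2 * np.pi * src.f_lo_hz * t)
    return out


def _source_truth(src: SourceSpec, spec: SceneSpec, on_device: bool) -> dict:
    att = 0.0
    if not src.rf_only:
        att = _attenuation_in_band(spec.enclosure_attenuation_db,
                                   src.f_lo_hz, max(src.f_hi_hz, src.f_lo_hz))
    if src.kind == "cal_tone":
        att = 0.0  # coupler seals over the microphone
    in_band = src.level_db_spl - att
    bg = _background_level_in(spec.background, src.f_lo_hz,
                              max(src.f_hi_hz, src.f_lo_hz + 1.0))
    if src.kind == "cal_tone":
        expected = in_band  # background muted during the tone
    else:
        expected = energy_sum_db([in_band, bg])
    return {
        "kind": src.kind,
        "label": src.label,
        "t_start_s": src.t_start_s,
        "t_end_s": src.t_end_s,
        "f_lo_hz": src.f_lo_hz,
        "f_hi_hz": src.f_hi_hz,
        "rf_only": src.rf_only,
        "on_device": on_device,
        "in_band_db_spl": in_band if on_device else None,
        "expected_measured_in_band_db_spl": expected if on_device else (
            bg if np.isfinite(bg) else None),
    }


def render_scene(spec: SceneSpec) -> tuple[RawRecording, dict]:
    """Render a scene to normalized counts plus a sidecar truth record.

    Deterministic given the seed: the same spec renders bit-identical
    samples.  Raises :class:`HeadroomError`, naming the loudest source, if
    any count reaches the 16-bit rail.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.rate_hz))

    cal_windows = [
        _sample_slice(s.t_start_s, s.t_end_s, spec.rate_hz, n)
        for s in spec.sources if s.kind == "cal_tone"
    ]

    # background: stationary over the scene, muted under the calibrator coupler
    background = np.zeros(n)
    active = np.ones(n, dtype=bool)
    for w in cal_windows:
        active[w] = False
    for seg in spec.background:
        noise = _band_noise(rng, n, spec.rate_hz, seg.f_lo_hz, seg.f_hi_hz)
        ms = float(np.mean(noise[active] ** 2))
        noise *= np.sqrt(_level_to_mean_square(seg.level_db_spl) / ms)
        background += noise
    background[~active] = 0.0

    acoustic = np.zeros(n)
    direct = np.zeros(n)  # calibration tone: at-the-microphone
    rf = np.zeros(n)
    peak_by_source: dict[str, float] = {}
    for i, src in enumerate(spec.sources):
        rendered = _render_source(src, spec, rng, n)
        name = src.label or f"{src.kind}#{i}"
        peak_by_source[name] = float(np.max(np.abs(rendered)))
        if src.rf_only:
            rf += rendered
        elif src.kind == "cal_tone":
            direct += rendered
        else:
            acoustic += rendered

    airborne = apply_enclosure(acoustic, spec.rate_hz,
                               spec.enclosure_attenuation_db)
    pressure = background + airborne + direct
    if spec.rf_susceptible:
        pressure = pressure + rf

    counts = pressure * spec.sensitivity_counts_per_pa
    if np.max(np.abs(counts)) >= 1.0:
        if peak_by_source:
            worst = max(peak_by_source, key=peak_by_source.get)
            culprit = (f"loudest source: {worst} "
                       f"(peak {peak_by_source[worst]:.1f} Pa)")
        else:
            culprit = "background noise"
        raise HeadroomError(
            f"rendered counts reach full scale ({spec.full_scale_pa:g} Pa); "
            f"{culprit}"
        )

    truth = {
        "schema_version": TRUTH_SCHEMA_VERSION,
        "seed": spec.seed,
        "rate_hz": spec.rate_hz,
        "duration_s": spec.duration_s,
        "sensitivity_counts_per_pa": spec.sensitivity_counts_per_pa,
        "full_scale_pa": spec.full_scale_pa,
        "enclosure_attenuation_db": spec.enclosure_attenuation_db,
        "rf_susceptible": spec.rf_susceptible,
        "background": [asdict(seg) for seg in spec.background],
        "sources": [_source_truth(s, spec, on_device=(spec.rf_susceptible
                                                      or not s.rf_only))
                    for s in spec.sources],
    }
    rec = RawRecording(samples=counts, rate_hz=spec.rate_hz, bit_depth=16,
                       label=spec.label or "synthetic scene")
    return rec, truth


def render_paired_devices(spec: SceneSpec) -> tuple[RawRecording, RawRecording, dict]:
    """Render the same acoustic scene on an RF-susceptible device (A) and an
    RF-immune reference device (B).

    RF-only sources appear on A regardless of enclosures and barriers;
    acoustic sources (e.g. the audible beep) appear identically on both.
    Raises a spec error when no RF-immune reference exists.
    """
    if not spec.rf_susceptible:
        raise ValueError("paired rendering needs spec.rf_susceptible device A")
    if not any(s.rf_only for s in spec.sources):
        spec_b = _with(spec, rf_susceptible=False, label=(spec.label + " [B]").strip())
        rec_a, truth = render_scene(spec)
        rec_b, _ = render_scene(spec_b)
        truth["paired"] = True
        return rec_a, rec_b, truth
    spec_b = _with(spec, rf_susceptible=False, label=(spec.label + " [B]").strip())
    rec_a, truth_a = render_scene(spec)
    rec_b, truth_b = render_scene(spec_b)
    truth = dict(truth_a)
    truth["paired"] = True
    truth["device_b_sources"] = truth_b["sources"]
    return rec_a, rec_b, truth


def _with(spec: SceneSpec, **kw) -> SceneSpec:
    payload = asdict(spec)
    payload["background"] = spec.background
    payload["sources"] = spec.sources
    payload.update(kw)
    return SceneSpec(**payload)


def scene_from_dict(payload: dict) -> SceneSpec:
    """Build a SceneSpec from a plain dict (YAML/JSON scene files)."""
    background = tuple(
        BackgroundSegment(**seg) for seg in payload.get("background", ())
    )
    sources = tuple(SourceSpec(**src) for src in payload.get("sources", ()))
    kwargs = {k: v for k, v in payload.items()
              if k not in ("background", "sources")}
    return SceneSpec(background=background, sources=sources, **kwargs)


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2)
        fh.write("\n")
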