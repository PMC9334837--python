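"""Absolute calibration of count streams against a 94 dB SPL reference tone.

Sound-level workflows anchor every measurement to a pistonphone-style
reference: a 1 kHz tone at 94 dB SPL (an RMS pressure of
20e-6 * 10**(94/20) ~= 1.0024 Pa).  Fitting that segment yields the device
sensitivity in normalized counts per pascal; dividing by it turns the count
stream into a pressure waveform on which all dB SPL (dB re 20 uPa) math is
defined.  A single-frequency calibration is treated as valid across the band,
appropriate for measurement microphones with a flat response over their
stated range; no frequency-response correction curve is modeled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace

import numpy as np
from scipy import signal as _signal

from .wav_io import RawRecording

__all__ = [
    "P_REF_PA",
    "REF_LEVEL_DB_SPL",
    "REF_FREQUENCY_HZ",
    "ref_pressure_rms_pa",
    "CalibrationModel",
    "CalibratedRecording",
    "CalibrationError",
    "fit_calibration",
    "apply_calibration",
    "spl_rms",
]

#: Reference pressure for dB SPL, 20 micropascals RMS.
P_REF_PA = 20e-6
REF_LEVEL_DB_SPL = 94.0
REF_FREQUENCY_HZ = 1000.0

#: Minimum ratio of tone power to residual power for a valid reference segment.
TONE_TO_RESIDUAL_MIN_DB = 20.0


def ref_pressure_rms_pa(level_db_spl: float = REF_LEVEL_DB_SPL) -> float:
    """RMS pressure in pascals for a given dB SPL level."""
    return P_REF_PA * 10.0 ** (level_db_spl / 20.0)


class CalibrationError(ValueError):
    """Raised when a reference-tone window fails the validity checks."""


@dataclass(frozen=True)
class CalibrationModel:
    """Mapping from normalized counts to pascals, anchored at 94 dB SPL / 1 kHz."""

    sensitivity_counts_per_pa: float
    ref_frequency_hz: float = REF_FREQUENCY_HZ
    ref_level_db_spl: float = REF_LEVEL_DB_SPL
    fit_rms_error_db: float = 0.0

    def __post_init__(self) -> None:
        s = self.sensitivity_counts_per_pa
        if not (np.isfinite(s) and s > 0):
            raise ValueError(f"sensitivity must be finite and > 0, got {s}")

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "CalibrationModel":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            try:
                payload = json.loads(source)
            except (ValueError, TypeError):
                with open(source) as fh:
                    payload = json.load(fh)
        return cls(**payload)


@dataclass(frozen=True)
class CalibratedRecording:
    """A pressure waveform in pascals with its sampling rate."""

    pressure_pa: np.ndarray
    rate_hz: float
    label: str = ""

    def __post_init__(self) -> None:
        p = np.asarray(self.pressure_pa, dtype=np.float64)
        if p.ndim != 1 or p.size < 1:
            raise ValueError("pressure_pa must be a non-empty 1-D array")
        if not np.all(np.isfinite(p)):
            raise ValueError("pressure_pa contains non-finite values")
        object.__setattr__(self, "pressure_pa", p)

    @property
    def nyquist_hz(self) -> float:
        return self.rate_hz / 2.0

    @property
    def duration_s(self) -> float:
        return self.pressure_pa.size / self.rate_hz

    def slice_time(self, t_start_s: float, t_end_s: float) -> "CalibratedRecording":
        i0 = int(round(t_start_s * self.rate_hz))
        i1 = int(round(t_end_s * self.rate_hz))
        if not (0 <= i0 < i1 <= self.pressure_pa.size):
            raise ValueError(f"window [{t_start_s}, {t_end_s}) s outside recording")
        return replace(self, pressure_pa=self.pressure_pa[i0:i1])


def _tone_to_residual_db(x: np.ndarray, rate_hz: float) -> tuple[float, float]:
    """Dominant frequency and tone-to-residual power ratio of a windowed FFT."""
    w = _signal.windows.hann(x.size, sym=False)
    spec = np.abs(np.fft.rfft((x - x.mean()) * w)) ** 2
    freqs = np.fft.rfftfreq(x.size, d=1.0 / rate_hz)
    k = int(np.argmax(spec[1:]) + 1)  # skip DC
    lo, hi = max(k - 3, 1), min(k + 4, spec.size)
    tone_power = float(spec[lo:hi].sum())
    residual = float(spec[1:].sum() - tone_power)
    ratio_db = 10.0 * np.log10(tone_power / max(residual, 1e-300))
    return float(freqs[k]), ratio_db


def fit_calibration(tone: RawRecording, tone_window: tuple[float, float],
                    ref_level_db_spl: float = REF_LEVEL_DB_SPL,
                    ref_frequency_hz: float = REF_FREQUENCY_HZ) -> CalibrationModel:
    """Fit counts-per-pascal sensitivity from a reference-tone window.

    The window must hold a quasi-stationary tone of at least 0.2 s whose
    dominant spectral component lies within 5% of the reference frequency and
    exceeds the residual by 20 dB; otherwise :class:`CalibrationError`.
    """
    t0, t1 = tone_window
    if t1 - t0 < 0.2:
        raise CalibrationError("reference-tone window shorter than 0.2 s")
    seg = tone.slice_time(t0, t1).samples
    f_peak, ratio_db = _tone_to_residual_db(seg, tone.rate_hz)
    if abs(f_peak - ref_frequency_hz) > 0.05 * ref_frequency_hz:
        raise CalibrationError(
            f"dominant component {f_peak:.1f} Hz not within 5% of "
            f"{ref_frequency_hz:.0f} Hz reference"
        )
    if ratio_db < TONE_TO_RESIDUAL_MIN_DB:
        raise CalibrationError(
            f"tone-to-residual ratio {ratio_db:.1f} dB < "
            f"{TONE_TO_RESIDUAL_MIN_DB:.0f} dB; window dominated by noise"
        )
    rms_counts = float(np.sqrt(np.mean(seg**2)))
    sensitivity = rms_counts / ref_pressure_rms_pa(ref_level_db_spl)
    # residual energy expressed as an RMS level error on the fit
    fit_err = 10.0 * np.log10(1.0 + 10.0 ** (-ratio_db / 10.0))
    return CalibrationModel(sensitivity_counts_per_pa=sensitivity,
                            ref_frequency_hz=ref_frequency_hz,
                            ref_level_db_spl=ref_level_db_spl,
                            fit_rms_error_db=float(fit_err))


def apply_calibration(rec: RawRecording, model: CalibrationModel) -> CalibratedRecording:
    """Convert normalized counts to pascals: pressure = counts / sensitivity."""
    return CalibratedRecording(
        pressure_pa=rec.samples / model.sensitivity_counts_per_pa,
        rate_hz=rec.rate_hz, label=rec.label)


def spl_rms(rec: CalibratedRecording,
            window: tuple[float, float] | None = None) -> float:
    """Broadband RMS sound pressure level, dB re 20 uPa.

    Returns ``-inf`` for an identically-zero window (below any measurement
    floor).  An empty window is a domain error.
    """
    seg = rec.pressure_pa if window is None else rec.slice_time(*window).pressure_pa
    rms = float(np.sqrt(np.mean(seg**2)))
    if rms == 0.0:
        return float("-inf")
    return 20.0 * np.log10(rms / P_REF_PA)
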