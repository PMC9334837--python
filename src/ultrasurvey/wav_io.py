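"""Read, write and pre-filter uncompressed PCM WAV audio.

High-sample-rate ultrasonic recorders (250 kHz and 384 kHz class devices)
store uncompressed 16-bit PCM mono WAV.  This module is the single point of
ingest: it normalizes integer counts to [-1, 1), keeps exact sample-rate and
bit-depth bookkeeping, and provides the zero-phase 10 kHz-style high-pass
used to pre-condition ultrasonic recordings.
"""

from __future__ import annotations

import logging
import wave
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal
from scipy.io import wavfile

__all__ = [
    "RawRecording",
    "UnsupportedFormatError",
    "read_wav",
    "write_wav",
    "high_pass",
]

log = logging.getLogger(__name__)

WAVE_FORMAT_PCM = 1


class UnsupportedFormatError(ValueError):
    """Raised for WAV files that are not uncompressed integer PCM."""


@dataclass(frozen=True)
class RawRecording:
    """A mono sample stream in normalized counts.

    Samples are integer PCM counts divided by ``2**(bit_depth - 1)``, so a
    full-scale negative count maps to exactly -1.0 and the positive rail to
    just below +1.0.
    """

    samples: np.ndarray
    rate_hz: float
    bit_depth: int = 16
    label: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not (self.rate_hz > 0):
            raise ValueError(f"rate_hz must be positive, got {self.rate_hz}")
        object.__setattr__(self, "samples", samples)

    @property
    def nyquist_hz(self) -> float:
        return self.rate_hz / 2.0

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate_hz

    def slice_time(self, t_start_s: float, t_end_s: float) -> "RawRecording":
        i0 = int(round(t_start_s * self.rate_hz))
        i1 = int(round(t_end_s * self.rate_hz))
        if not (0 <= i0 < i1 <= self.samples.size):
            raise ValueError(f"window [{t_start_s}, {t_end_s}) s outside recording")
        return replace(self, samples=self.samples[i0:i1])


def _probe_format(path) -> None:
    """Reject non-PCM containers with a clear error before decoding."""
    try:
        with wave.open(str(path), "rb") as fh:
            # wave raises on compressed formats it cannot parse; WAVE_FORMAT_EXTENSIBLE
            # and float PCM fall through to scipy below.
            comp = fh.getcomptype()
            if comp != "NONE":
                raise UnsupportedFormatError(
                    f"{path}: compression type {comp!r} is not uncompressed PCM"
                )
    except wave.Error as exc:
        if "unknown format" in str(exc).lower():
            raise UnsupportedFormatError(f"{path}: {exc}") from exc
        # Other wave parse errors (e.g. extensible headers) are retried by scipy.


def read_wav(path) -> RawRecording:
    """Read an uncompressed integer-PCM WAV file as a :class:`RawRecording`.

    Multi-channel files are reduced to channel 0 with a warning; surveys use
    single microphones.  Compressed or floating-point WAV raises
    :class:`UnsupportedFormatError`.
    """
    _probe_format(path)
    try:
        rate, data = wavfile.read(str(path))
    except ValueError as exc:
        raise UnsupportedFormatError(f"{path}: {exc}") from exc
    if data.dtype.kind == "f":
        raise UnsupportedFormatError(f"{path}: float PCM is not supported")
    if data.dtype == np.uint8:
        bit_depth = 8
        counts = data.astype(np.float64) - 128.0
    elif data.dtype == np.int16:
        bit_depth = 16
        counts = data.astype(np.float64)
    elif data.dtype == np.int32:
        bit_depth = 32
        counts = data.astype(np.float64)
    else:
        raise UnsupportedFormatError(f"{path}: unsupported sample dtype {data.dtype}")
    if counts.ndim > 1:
        log.warning("%s: %d channels, keeping channel 0", path, counts.shape[1])
        counts = counts[:, 0]
    samples = counts / float(2 ** (bit_depth - 1))
    return RawRecording(samples=samples, rate_hz=float(rate), bit_depth=bit_depth,
                        label=str(path))


def write_wav(rec: RawRecording, path) -> str:
    """Write a recording as 16-bit PCM mono WAV; returns the path written.

    Counts are rounded to the nearest integer and clipped to the 16-bit rails,
    so a read-back differs from the input by at most one quantization step.
    """
    if np.max(np.abs(rec.samples)) > 1.0:
        raise ValueError("samples exceed [-1, 1]; refusing to clip on write")
    counts = np.round(rec.samples * 32768.0)
    counts = np.clip(counts, -32768, 32767).astype(np.int16)
    wavfile.write(str(path), int(round(rec.rate_hz)), counts)
    return str(path)


def high_pass(rec: RawRecording, cutoff_hz: float) -> RawRecording:
    """Zero-phase high-pass filter (forward-backward Butterworth).

    A 12th-order Butterworth applied with ``sosfiltfilt`` gives > 60 dB
    rejection one octave below the cutoff and < 0.1 dB ripple above
    1.25x the cutoff, while the forward-backward pass preserves event timing.
    ``cutoff_hz == 0`` is the identity.
    """
    if cutoff_hz < 0 or cutoff_hz >= rec.nyquist_hz:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz outside (0, nyquist={rec.nyquist_hz} Hz)"
        )
    if cutoff_hz == 0:
        return replace(rec, samples=rec.samples.copy())
    sos = signal.butter(12, cutoff_hz, btype="highpass", fs=rec.rate_hz,
                        output="sos")
    filtered = signal.sosfiltfilt(sos, rec.samples)
    return replace(rec, samples=filtered,
                   label=f"{rec.label} [hp {cutoff_hz:g} Hz]".strip())
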