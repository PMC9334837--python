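"""Analyser-style FFT autospectra in one-second epochs, plus fine-frame views.

The measurement convention mirrors a laboratory FFT sound analyser: linear
(unweighted) autospectra of 6400 lines over 0-100 kHz, refreshed every
second, with levels in dB SPL (dB re 20 uPa).  Each epoch is Welch-averaged
from Hann-windowed, 50%-overlapped segments whose length is chosen so the
bin width equals ``span / n_lines`` (15.625 Hz for the standard
configuration).  Bin values carry the energy in that bin (power spectral
density times bin width, energy-normalized for the window), so band sums are
Parseval-consistent with the time-domain RMS level and a stationary tone's
level is recovered by summing the few bins of its main lobe.

Impulsive and frequency-modulated structure that a 1 s epoch cannot resolve
is examined with :func:`fine_spectrogram` (5 ms Hann frames by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .calibration import CalibratedRecording, P_REF_PA

__all__ = [
    "AutoSpectrum",
    "Spectrogram",
    "FineSpectrogram",
    "autospectrum",
    "spectrogram",
    "peak_epoch",
    "fine_spectrogram",
    "DEFAULT_N_LINES",
    "DEFAULT_SPAN_HZ",
]

DEFAULT_N_LINES = 6400
DEFAULT_SPAN_HZ = 100_000.0
EPOCH_SECONDS = 1.0


@dataclass(frozen=True)
class AutoSpectrum:
    """Single-sided autospectrum of one epoch, per-bin levels in dB SPL."""

    bin_freqs_hz: np.ndarray
    bin_levels_db_spl: np.ndarray
    epoch_index: int
    n_lines: int
    span_hz: float
    epoch_seconds: float = EPOCH_SECONDS

    @property
    def bin_width_hz(self) -> float:
        return float(self.bin_freqs_hz[1] - self.bin_freqs_hz[0])


@dataclass(frozen=True)
class Spectrogram:
    """Ordered one-second epochs with their start times."""

    epochs: tuple[AutoSpectrum, ...]
    times_s: np.ndarray

    @property
    def bin_freqs_hz(self) -> np.ndarray:
        return self.epochs[0].bin_freqs_hz

    def level_matrix(self) -> np.ndarray:
        """(n_epochs, n_bins) matrix of bin levels in dB SPL."""
        return np.vstack([e.bin_levels_db_spl for e in self.epochs])


@dataclass(frozen=True)
class FineSpectrogram:
    """Short-frame STFT levels for transient / FM structure (frames x bins)."""

    times_s: np.ndarray
    bin_freqs_hz: np.ndarray
    levels_db_spl: np.ndarray  # shape (n_frames, n_bins)
    frame_seconds: float

    def level_matrix(self) -> np.ndarray:
        return self.levels_db_spl


def _levels_db(psd: np.ndarray, bin_width_hz: float) -> np.ndarray:
    """Per-bin energy level in dB SPL from a one-sided PSD."""
    with np.errstate(divide="ignore"):
        return 10.0 * np.log10(psd * bin_width_hz / P_REF_PA**2)


def _segment_length(rate_hz: float, span_hz: float, n_lines: int) -> int:
    """Welch segment length giving a bin width of span/n_lines (rounded)."""
    return int(round(rate_hz / (span_hz / n_lines)))


def autospectrum(rec: CalibratedRecording, epoch_start_s: float = 0.0,
                 n_lines: int = DEFAULT_N_LINES,
                 span_hz: float = DEFAULT_SPAN_HZ,
                 epoch_index: int | None = None) -> AutoSpectrum:
    """Welch-averaged autospectrum of the 1 s epoch starting at ``epoch_start_s``.

    Raises a domain error when ``span_hz`` exceeds Nyquist and a short-epoch
    error when the epoch extends past the end of the recording.  For rates
    where an integer segment length cannot hit the requested bin width
    exactly, the length is rounded and the actual bin grid used.
    """
    if span_hz > rec.nyquist_hz:
        raise ValueError(
            f"span {span_hz} Hz exceeds Nyquist {rec.nyquist_hz} Hz"
        )
    t_end = epoch_start_s + EPOCH_SECONDS
    if t_end > rec.duration_s + 0.5 / rec.rate_hz:
        raise ValueError(
            f"epoch [{epoch_start_s}, {t_end}) s extends past recording end "
            f"({rec.duration_s:.3f} s)"
        )
    x = rec.slice_time(epoch_start_s, t_end).pressure_pa
    nperseg = _segment_length(rec.rate_hz, span_hz, n_lines)
    if nperseg > x.size:
        raise ValueError("epoch shorter than one analysis segment")
    freqs, psd = signal.welch(
        x, fs=rec.rate_hz, window="hann", nperseg=nperseg,
        noverlap=nperseg // 2, detrend=False, scaling="density")
    bin_width = float(freqs[1] - freqs[0])
    keep = freqs <= span_hz + 0.5 * bin_width
    # n_lines+1 points from DC through span when the grid divides evenly
    keep &= np.arange(freqs.size) <= n_lines
    return AutoSpectrum(
        bin_freqs_hz=freqs[keep],
        bin_levels_db_spl=_levels_db(psd[keep], bin_width),
        epoch_index=0 if epoch_index is None else epoch_index,
        n_lines=n_lines, span_hz=span_hz)


def spectrogram(rec: CalibratedRecording, n_lines: int = DEFAULT_N_LINES,
                span_hz: float = DEFAULT_SPAN_HZ) -> Spectrogram:
    """One autospectrum per whole second; a trailing partial second is dropped."""
    n_epochs = int(np.floor(rec.duration_s / EPOCH_SECONDS))
    if n_epochs < 1:
        raise ValueError(f"recording of {rec.duration_s:.3f} s is shorter than 1 s")
    epochs = tuple(
        autospectrum(rec, epoch_start_s=i * EPOCH_SECONDS, n_lines=n_lines,
                     span_hz=span_hz, epoch_index=i)
        for i in range(n_epochs)
    )
    return Spectrogram(epochs=epochs,
                       times_s=np.arange(n_epochs, dtype=float) * EPOCH_SECONDS)


def peak_epoch(spec: Spectrogram, band) -> AutoSpectrum:
    """The epoch with the highest band level; ties resolved to the earliest.

    This is how impulsive events are characterized: the one-second record at
    the highest level of the impact is the one reported.
    """
    from .band_metrics import band_level

    levels = [band_level(e, band) for e in spec.epochs]
    return spec.epochs[int(np.argmax(levels))]


def fine_spectrogram(rec: CalibratedRecording, frame_s: float = 0.005,
                     overlap: float = 0.5) -> FineSpectrogram:
    """Short-frame Hann STFT up to Nyquist for transient / FM structure.

    Frames longer than 10 ms cannot resolve the modulation of FM bursts;
    the default 5 ms frame gives a 200 Hz grid at 250 kHz.
    """
    if not (0 < frame_s <= 0.010):
        raise ValueError("frame_s must be in (0, 0.010] s to resolve modulation")
    nperseg = int(round(frame_s * rec.rate_hz))
    noverlap = int(round(nperseg * overlap))
    freqs, times, psd = signal.spectrogram(
        rec.pressure_pa, fs=rec.rate_hz, window="hann", nperseg=nperseg,
        noverlap=noverlap, detrend=False, scaling="density", mode="psd")
    bin_width = float(freqs[1] - freqs[0])
    return FineSpectrogram(
        times_s=times, bin_freqs_hz=freqs,
        levels_db_spl=_levels_db(psd.T, bin_width),
        frame_seconds=frame_s)
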