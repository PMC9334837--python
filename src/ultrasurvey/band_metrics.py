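"""Named-band SPL integration, background correction and difference tables.

The analyser-style "delta cursor" sums bin energies between two frequencies
and reports one SPL.  The standard survey band set spans the microphone range
(Total, 4 Hz-100 kHz), the human audible range (20 Hz-20 kHz), the mouse peak
hearing-sensitivity range (10-20 kHz) and the ultrasonic range (20-100 kHz).
Band edges are half-open [lo, hi) on bin centers so that bands sharing a
boundary frequency (mouse peak / ultrasonic at 20 kHz) never double-count a
bin, and bins below 4 Hz are excluded from all band math (outside the
measurement microphone's range).

Background correction is energy subtraction,
``10*log10(10**(L_meas/10) - 10**(L_bg/10))``, flagged unreliable when the
measured level sits within 3 dB of background (standard acoustics practice:
below a 3 dB separation — a doubling of sound pressure — the source estimate
is background-limited and only an upper bound is reported).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Band",
    "STANDARD_BANDS",
    "MIN_VALID_FREQ_HZ",
    "BandLevelTable",
    "CorrectionResult",
    "band_level",
    "background_correct",
    "difference_table",
    "reduction_table",
    "attenuation_estimate",
    "energy_sum_db",
]

#: Bins below this frequency are ignored in all band integrations.
MIN_VALID_FREQ_HZ = 4.0

#: Minimum measured-minus-background separation for a reliable correction.
CORRECTION_MIN_SEPARATION_DB = 3.0


@dataclass(frozen=True)
class Band:
    name: str
    f_lo_hz: float
    f_hi_hz: float

    def __post_init__(self) -> None:
        if not (self.f_lo_hz < self.f_hi_hz):
            raise ValueError(f"band {self.name}: f_lo must be < f_hi")


STANDARD_BANDS: tuple[Band, ...] = (
    Band("Total", 4.0, 100_000.0),
    Band("Human audible", 20.0, 20_000.0),
    Band("Mouse peak", 10_000.0, 20_000.0),
    Band("Ultrasonic", 20_000.0, 100_000.0),
)


def energy_sum_db(levels_db: Iterable[float]) -> float:
    """Energy sum of dB levels: 10*log10(sum 10**(L/10)). -inf inputs are ignored."""
    arr = np.asarray(list(levels_db), dtype=float)
    arr = arr[np.isfinite(arr) | (arr == np.inf)]
    if arr.size == 0:
        return float("-inf")
    total = np.sum(10.0 ** (arr / 10.0))
    return float(10.0 * np.log10(total)) if total > 0 else float("-inf")


def band_level(spec, band: Band) -> float:
    """Delta-cursor band level: energy sum of bins with centers in [lo, hi).

    ``spec`` is any object exposing ``bin_freqs_hz`` and ``bin_levels_db_spl``
    (an :class:`~ultrasurvey.spectral.AutoSpectrum`).  Bins below 4 Hz are
    always excluded.  An empty bin selection is a domain error.
    """
    freqs = np.asarray(spec.bin_freqs_hz, dtype=float)
    levels = np.asarray(spec.bin_levels_db_spl, dtype=float)
    mask = (freqs >= max(band.f_lo_hz, MIN_VALID_FREQ_HZ)) & (freqs < band.f_hi_hz)
    if not np.any(mask):
        raise ValueError(
            f"band {band.name} [{band.f_lo_hz}, {band.f_hi_hz}) Hz selects no bins"
        )
    return energy_sum_db(levels[mask])


@dataclass(frozen=True)
class CorrectionResult:
    corrected_db_spl: float
    status: str  # "ok" | "background_limited"


def background_correct(l_meas_db: float, l_bg_db: float) -> CorrectionResult:
    """Energy-subtraction background correction with a 3 dB validity rule.

    When the measured level exceeds background by at least 3 dB the corrected
    source level is returned with status ``ok``; otherwise the estimate is
    background-limited and the upper bound ``l_meas - 3`` dB is reported.
    A background of ``-inf`` means no background energy: the measured level is
    returned unchanged.
    """
    if np.isnan(l_meas_db) or np.isnan(l_bg_db):
        raise ValueError("levels must not be NaN")
    if l_bg_db == float("-inf"):
        return CorrectionResult(float(l_meas_db), "ok")
    if l_meas_db - l_bg_db < CORRECTION_MIN_SEPARATION_DB:
        return CorrectionResult(float(l_meas_db) - CORRECTION_MIN_SEPARATION_DB,
                                "background_limited")
    corrected = 10.0 * np.log10(10.0 ** (l_meas_db / 10.0) - 10.0 ** (l_bg_db / 10.0))
    return CorrectionResult(float(corrected), "ok")


class BandLevelTable:
    """Per-band background/measured levels with derived difference columns.

    Backed by a :class:`pandas.DataFrame` indexed by band name with columns
    ``f_lo_hz, f_hi_hz, background_db_spl, measured_db_spl, difference_db_spl``
    and, when two conditions are compared, ``reduction_db_spl``.  Difference
    and reduction are exact arithmetic on the stored values; no background
    correction is applied (for high-level impulsive noise the correction is
    negligible and the raw difference is the reported quantity).
    """

    COLUMNS = ("f_lo_hz", "f_hi_hz", "background_db_spl", "measured_db_spl",
               "difference_db_spl", "reduction_db_spl")

    def __init__(self, frame: pd.DataFrame):
        missing = {"background_db_spl", "measured_db_spl"} - set(frame.columns)
        if missing:
            raise ValueError(f"band table missing columns: {sorted(missing)}")
        self.frame = frame.copy()

    @property
    def bands(self) -> tuple[str, ...]:
        return tuple(self.frame.index)

    def __getitem__(self, band_name: str) -> pd.Series:
        return self.frame.loc[band_name]

    def __eq__(self, other) -> bool:
        return isinstance(other, BandLevelTable) and self.frame.equals(other.frame)

    def to_csv(self, path) -> None:
        self.frame.rename_axis("band").to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "BandLevelTable":
        frame = pd.read_csv(path, float_precision="round_trip")
        if "band" not in frame.columns:
            raise ValueError(f"{path}: missing 'band' column")
        return cls(frame.set_index("band").rename_axis(None))

    def to_json(self) -> str:
        return self.frame.rename_axis("band").reset_index().to_json(orient="records")


def _check_bands(levels: Mapping[str, float], bands: tuple[Band, ...]) -> None:
    missing = [b.name for b in bands if b.name not in levels]
    if missing:
        raise ValueError(f"missing levels for bands: {missing}")


def difference_table(background: Mapping[str, float], measured: Mapping[str, float],
                     bands: tuple[Band, ...] = STANDARD_BANDS) -> BandLevelTable:
    """Build a one-condition table with the per-band measured-minus-background column."""
    _check_bands(background, bands)
    _check_bands(measured, bands)
    rows = {
        b.name: {
            "f_lo_hz": b.f_lo_hz,
            "f_hi_hz": b.f_hi_hz,
            "background_db_spl": float(background[b.name]),
            "measured_db_spl": float(measured[b.name]),
            "difference_db_spl": float(measured[b.name]) - float(background[b.name]),
        }
        for b in bands
    }
    return BandLevelTable(pd.DataFrame.from_dict(rows, orient="index"))


def reduction_table(cond_a: BandLevelTable, cond_b: BandLevelTable) -> BandLevelTable:
    """Per-band reduction: difference(A) - difference(B), e.g. metal vs neoprene mat."""
    if cond_a.bands != cond_b.bands:
        raise ValueError(
            f"band mismatch: {cond_a.bands} vs {cond_b.bands}"
        )
    frame = cond_a.frame.copy()
    frame["reduction_db_spl"] = (
        cond_a.frame["difference_db_spl"] - cond_b.frame["difference_db_spl"]
    )
    return BandLevelTable(frame)


def attenuation_estimate(outside: BandLevelTable,
                         inside: BandLevelTable) -> pd.DataFrame:
    """Per-band enclosure attenuation of the same event measured in two positions.

    attenuation = outside.measured - inside.measured; negative estimates
    (measurement noise) are clamped to 0 dB and flagged.
    """
    if outside.bands != inside.bands:
        raise ValueError(f"band mismatch: {outside.bands} vs {inside.bands}")
    raw = outside.frame["measured_db_spl"] - inside.frame["measured_db_spl"]
    return pd.DataFrame({
        "attenuation_db": raw.clip(lower=0.0),
        "clamped": raw < 0.0,
    })
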