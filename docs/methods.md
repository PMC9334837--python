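# Methods

## Measurement model

All levels are sound pressure levels in dB re 20 µPa (RMS), linear
(unweighted).  A-weighting is deliberately absent: it models human loudness
over the audible band and says nothing about a mouse's 1–100 kHz hearing
range.  A recording enters the pipeline as normalized integer counts
(`counts / 2^(bit_depth−1)`, so the negative 16-bit rail maps to −1.0);
a reference-tone segment — 1 kHz at 94 dB SPL, the standard pistonphone
output — fixes the sensitivity

    sensitivity = RMS(counts in window) / (20e−6 · 10^(94/20))  [counts/Pa]

and division by it yields the pressure waveform every level is computed
from.  Single-frequency calibration is treated as valid across the band, the
appropriate assumption for a measurement microphone with a flat response
over its stated range; no frequency-response correction curve is modeled.
A calibration window must hold a quasi-stationary tone of ≥ 0.2 s whose
dominant component lies within 5 % of 1 kHz and exceeds the spectral
residual by 20 dB — the threshold that reliably rejects a window of facility
background accidentally passed as a calibration segment.

## Epoch spectra

The spectral front end mirrors a laboratory FFT analyser: autospectra of
`n_lines = 6400` bins spanning 0–100 kHz (bin width 15.625 Hz), one per
one-second epoch, with a trailing partial second dropped.  Each epoch is
Welch-averaged from Hann-windowed segments of
`N = round(rate / (span/n_lines))` samples at 50 % overlap (≈30 averages per
epoch at 250 kHz); for rates where `N` does not divide the bin width
exactly, `N` is rounded and the actual bin grid used.  Bin values carry the
*energy* in the bin — one-sided PSD × bin width with the window's energy
correction — so that

* band sums are Parseval-consistent with the time-domain RMS level
  (verified to ≤ 0.2 dB over seeded scenes), and
* a stationary tone's level is recovered by summing the few bins of its
  Hann main lobe (±3 bins captures > 99.9 % of tone energy).

Reading a tone's level off the single peak bin would instead need amplitude
correction; every consumer in this package integrates energy over bins, so
the energy convention is used throughout.  Bins centered below 4 Hz are
masked from all band arithmetic (outside the measurement microphone's
range).  Transient and FM structure that a 1 s epoch cannot resolve is
examined on a separate short-frame spectrogram (5 ms Hann frames, 50 %
overlap, full Nyquist span).

## Band metrics

Delta-cursor band levels integrate bin energies over `[f_lo, f_hi)` —
half-open on bin centers, so bands sharing a boundary (mouse peak /
ultrasonic at 20 kHz) never double-count a bin.  Background correction is
energy subtraction with a 3 dB validity rule: below a 3 dB separation — a
doubling of sound pressure, the conventional just-noticeable step — the
source estimate is unreliable and only the upper bound `measured − 3 dB` is
reported, with status `background_limited`.  Difference and reduction tables
are exact arithmetic on their inputs; no background correction is applied to
impulsive-noise differences, where the measured level exceeds background by
>10 dB and the correction would change nothing at printed precision.  Levels
are stored at full precision and reported to 0.01 dB; comparisons against
published tables happen at each cell's printed precision.

## Event detection

Three detectors cover the survey's source types.  Their thresholds differ
by analysis view because the level statistics differ:

* **Tonal** (1 s epochs): the per-bin spectra are Welch averages of ~30
  segments, so bin levels fluctuate by well under 1 dB; a persistent
  **3 dB** excess — the doubling-of-pressure step — is a dependable margin.
  Levels are lightly smoothed across 3 bins (energy domain), thresholded
  against the smoothed background median, morphologically closed (gaps of
  ≤ 2 bins / ≤ 1 epoch), and connected regions lasting ≥ 3 s and narrower
  than 10 kHz become events.  The persistence requirement is what controls
  false positives; on pure-background scenes the detector is quiet at well
  under one event per hundred epochs.
* **Impact** (1 s epochs): super-threshold bins (≥ **10 dB** excess, no
  smoothing) must span ≥ 50 kHz, for at most two consecutive epochs.  The
  event is characterized at its peak epoch and carries per-standard-band
  excesses.
* **FM** (5 ms frames): single unaveraged periodogram bins fluctuate by
  several dB (an exponential power distribution), so ridge candidates use a
  **12 dB** excess plus a ≥ 5-frame persistence requirement.  Narrowband
  clusters are linked frame-to-frame when their energy-weighted centers move
  ≤ 2 kHz (tolerating 2-frame dropouts); a ridge whose center travels
  ≥ 1 kHz is `fm`, otherwise `tonal`.  Simultaneous ridges share a
  `group_id`.  An FM event's frequency extent is its center range — the
  modulation span — not the width of its spectral skirt.

The background model is the per-bin median over designated background
epochs (≥ 3 required) with an MAD-based spread; the median tolerates a
contaminated epoch.

**RF screening** implements the cross-device argument: electromagnetic
pickup travels through walls and enclosures, sound does not.  An ultrasonic
event on the RF-susceptible device with no time/frequency-overlapping
counterpart on the RF-immune reference is flagged `suspected_rf` — but only
when the reference *could* have detected it (the level expected at the
reference, A's peak minus a configurable device offset, clears the
reference's background in the event band by its detection threshold).
Audible-band events are exempt.  `barrier_plausibility` applies the same
physics to enclosures: an inside level within `expected_attenuation − 3 dB`
of the outside level is implausibly lossless propagation and flags
`through_barrier`; any inside detection flags `inside_ivc_audible`.

## Synthetic scenes

The generator renders the survey's study conditions as calibrated pressure
waveforms: a muting pistonphone segment (the coupler seals over the
microphone, so the facility background vanishes during the tone), stationary
piecewise-flat background noise with per-band targets, band-limited Gaussian
narrowband sources (the ceiling-light emission at 40.3–47.4 kHz — modeled as
band-limited noise, since the available evidence does not resolve tonal
sidestructure), exponentially decaying broadband transients shaped per band
(forceps impacts), swept-sinusoid FM bursts plus an audible beep
(walkie-talkie operation), and an enclosure that attenuates airborne
*sources* — the configured background is the ambient at the microphone's own
position, and RF-only components bypass the enclosure entirely, appearing
only on RF-susceptible devices.

Published band readings arrive as levels in four overlapping bands; they are
converted to energies on the disjoint partition 4–20 Hz / 20 Hz–10 kHz /
10–20 kHz / 20–100 kHz by energy subtraction, clamping a negative remainder
(possible at printed precision) to zero.  Impact components are shaped to
the energy difference between the measured and background rows, so the
rendered measured epoch — background plus transient — reproduces the
measured row.  Every noise component is synthesized in the FFT domain
(exactly band-limited) and normalized to its target energy, so rendered
levels are exact rather than realizations with sampling variance; the
residual spread seen by the analysis is measurement noise only.

Numerical choices that matter:

* **Impact decay constant: 60 ms** (default).  Long enough that the
  transient's crest stays clear of the 16-bit rail at the published impact
  levels while the quantization floor stays ≥ 14 dB under the quietest band
  target; short enough that the event is confined to one 1 s epoch and
  clearly transient on 5 ms frames.
* **Crest limiting and re-bandlimiting.**  Impact noise is clipped at 3.3 σ
  (bounding the peak deterministically) and re-bandlimited *after*
  enveloping: both the clipping distortion and the onset-step sidebands
  would otherwise spill a 1/f² skirt into quiet neighbouring bands.  5 ms
  raised-cosine edge tapers prevent the window-truncation skirt, whose level
  rides on the random edge samples, from swamping those bands.
* **Edge guard (625 Hz).**  Band partitions used for synthesis end 40
  analysis bins below a shared band edge: the Welch near-lobe skirt of a
  100+ dB transient ending exactly at 10 kHz would otherwise leak into the
  bins the half-open convention assigns to the quiet mouse-peak band.  The
  guard costs < 0.03 dB of segment energy.
* **Full-scale pressure per scene** (4 Pa default; 250 Pa for impact
  scenes).  The reference tone recovers the resulting sensitivity, so
  absolute levels are unaffected; the choice only positions the 16-bit
  quantization floor.

Fixture timings: lights scenes are 26 s (calibration 0–2 s, lights on
12–22 s); forceps scenes 8 s (transient in epoch 4, background epochs 2–3
and 5–7); walkie-talkie scenes carry three 0.4 s bursts at 2 s intervals.
These sizes keep a full suite run under a minute while leaving ≥ 3 clean
background epochs per scene, the minimum the background model accepts.

## What the generator does and does not emulate

It reproduces the *level structure* of the study conditions — per-band
epoch levels, band extents, timing, enclosure attenuation, device RF
susceptibility — with exact truth sidecars.  It does not model room
acoustics (reverberation, directionality), microphone polar patterns or
frequency response, the true crest factor or spectral tilt of a real metal
impact (only per-band epoch levels are matched), or the real facility
background's spectral shape (piecewise-flat density per band).  Passing
tests therefore demonstrate that the measurement and detection chain is
correct and calibrated, not that any particular facility is quiet.

## Known limitations

* **16-bit dynamic range.**  A metal-impact scene peaks near 141 dB SPL
  while its ultrasonic background sits at ~41 dB SPL across 80 kHz; no
  16-bit WAV can carry both, so a WAV round trip of that scene raises the
  quiet ultrasonic background by ~2 dB (the coding floor).  The float
  pipeline and the rendered scenes are unaffected; analyser-style live
  measurement, which this package models, does not pass through 16-bit
  storage.  The CLI test suite bounds rather than asserts that one cell.
* **Absolute calibration of real recordings.**  Field recorders with
  unknown gain provide only relative levels; `survey --relative` reports
  dB re digital full scale and labels the output accordingly.  Absolute
  dB SPL requires a recorded reference tone or a calibration JSON.
* The published inside-IVC background row is internally inconsistent as
  absolute levels (a sub-band exceeding its superset); it is used for table
  arithmetic as printed, and the inside-IVC synthetic fixture is instead
  generated by applying a flat 10 dB enclosure to the metal scene.
* Neural-network call classification (e.g. syllable typing of mouse
  vocalizations) and vibration measurement are out of scope.
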