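"""Reference band levels from a mouse-facility ultrasonic noise survey.

These are the published delta-cursor readings the analysis pipeline
reproduces: per-band background and measured levels (dB SPL re 20 uPa,
1 s peak epochs) for metal forceps dropped onto a laminar-flow cabinet
surface, the same drop onto a neoprene mat, and the same drop measured from
inside an individually ventilated cage (IVC); plus the ceiling-light
delta-cursor readings.  They serve as inputs: the difference, reduction and
attenuation columns are always recomputed, never stored.
"""

from __future__ import annotations

from .band_metrics import STANDARD_BANDS

__all__ = [
    "FORCEPS_METAL_BG", "FORCEPS_METAL_MEASURED",
    "FORCEPS_NEOPRENE_BG", "FORCEPS_NEOPRENE_MEASURED",
    "FORCEPS_IVC_BG", "FORCEPS_IVC_MEASURED",
    "PUBLISHED_DIFFERENCES", "PUBLISHED_REDUCTIONS",
    "LIGHTS_DELTA_BAND_HZ", "LIGHTS_ON_DB", "LIGHTS_OFF_DB",
    "LIGHTS_PUBLISHED_CORRECTED_DB",
]

_BANDS = tuple(b.name for b in STANDARD_BANDS)

# Forceps dropped on the metal LAF-cabinet surface, microphone outside the IVC
FORCEPS_METAL_BG = {
    "Total": 85.96, "Human audible": 85.91, "Mouse peak": 43.83,
    "Ultrasonic": 40.63,
}
FORCEPS_METAL_MEASURED = {
    "Total": 112.11, "Human audible": 112.03, "Mouse peak": 97.71,
    "Ultrasonic": 89.97,
}

# Same drop cushioned by a neoprene mat
FORCEPS_NEOPRENE_BG = {
    "Total": 88.67, "Human audible": 87.87, "Mouse peak": 45.24,
    "Ultrasonic": 41.23,
}
FORCEPS_NEOPRENE_MEASURED = {
    "Total": 100.34, "Human audible": 100.36, "Mouse peak": 62.26,
    "Ultrasonic": 54.5,
}

# Metal-surface drop measured from inside the IVC.  Note the published BG
# rows are not mutually consistent as absolute levels (the human-audible
# sub-band exceeds the Total band); they are reproduced as printed and used
# only for table arithmetic, never for synthesis.
FORCEPS_IVC_BG = {
    "Total": 65.4, "Human audible": 79.7, "Mouse peak": 36.0,
    "Ultrasonic": 40.2,
}
FORCEPS_IVC_MEASURED = {
    "Total": 102.3, "Human audible": 104.1, "Mouse peak": 83.4,
    "Ultrasonic": 76.4,
}

# Published derived columns, kept only for verification of the recomputation
PUBLISHED_DIFFERENCES = {
    "metal": {"Total": 26.15, "Human audible": 26.12, "Mouse peak": 53.88,
              "Ultrasonic": 49.34},
    "neoprene": {"Total": 11.67, "Human audible": 12.49, "Mouse peak": 17.02,
                 "Ultrasonic": 13.27},
    "ivc": {"Total": 36.9, "Human audible": 24.4, "Mouse peak": 47.4,
            "Ultrasonic": 36.2},
}
PUBLISHED_REDUCTIONS = {
    "Total": 14.48, "Human audible": 13.63, "Mouse peak": 36.86,
    "Ultrasonic": 36.07,
}

# Fluorescent ceiling lights: delta cursor spanning the emission band
LIGHTS_DELTA_BAND_HZ = (40_300.0, 47_400.0)
LIGHTS_ON_DB = 33.1
LIGHTS_OFF_DB = 29.0
LIGHTS_PUBLISHED_CORRECTED_DB = 30.8  # computed from an off-level of ~29 dB
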