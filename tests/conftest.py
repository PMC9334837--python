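"""Shared fixtures: rendered synthetic scenes and their survey measurements.

Scenes are session-scoped — rendering a 250 kHz scene and running the epoch
analysis costs seconds, and every test that needs one can share it.
"""

from __future__ import annotations

import numpy as np
import pytest

from ultrasurvey import (Spectrogram, apply_calibration, fit_calibration,
                         spectrogram)
from ultrasurvey.event_detection import fit_background
from ultrasurvey.fixtures import (forceps_scene, lights_scene,
                                  walkie_talkie_paired_scene)

SEED = 101


def analyse(fx: dict, background_epochs) -> dict:
    """Calibrate, spectrogram and background-fit one rendered scene."""
    rec = fx["recording"]
    model = fit_calibration(rec, fx["cal_window_s"])
    cal = apply_calibration(rec, model)
    spg = spectrogram(cal)
    bg = fit_background(spg, background_epochs)
    analysis_idx = list(range(2, len(spg.epochs)))  # drop calibration epochs
    sub = Spectrogram(
        epochs=tuple(spg.epochs[i] for i in analysis_idx),
        times_s=np.asarray(spg.times_s)[analysis_idx])
    return {**fx, "calibration": model, "calibrated": cal, "spectrogram": spg,
            "background_model": bg, "analysis_spectrogram": sub}


@pytest.fixture(scope="session")
def lights():
    fx = lights_scene(seed=SEED)
    return analyse(fx, fx["off_epochs"])


@pytest.fixture(scope="session")
def lights_inside_ivc():
    fx = lights_scene(seed=SEED, source_attenuation_db=30.0)
    return analyse(fx, fx["off_epochs"])


@pytest.fixture(scope="session")
def forceps_metal():
    fx = forceps_scene(seed=SEED, condition="metal")
    return analyse(fx, fx["background_epochs"])


@pytest.fixture(scope="session")
def forceps_neoprene():
    fx = forceps_scene(seed=SEED, condition="neoprene")
    return analyse(fx, fx["background_epochs"])


@pytest.fixture(scope="session")
def forceps_inside_ivc():
    fx = forceps_scene(seed=SEED, condition="metal", enclosure_db=10.0)
    return analyse(fx, fx["background_epochs"])


@pytest.fixture(scope="session")
def walkie_paired():
    return walkie_talkie_paired_scene(seed=SEED)
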