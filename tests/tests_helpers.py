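"""Small shared helpers for the detection tests."""

import numpy as np

from ultrasurvey import (Spectrogram, apply_calibration, fit_calibration,
                         spectrogram)
from ultrasurvey.event_detection import fit_background
from ultrasurvey.scenes import render_scene


def analyse_scene(scene_spec, background_epochs=None, cal_window=(0.0, 2.0)):
    """Render a scene and return (spectrogram, background model, analysis view).

    The analysis view drops the calibration-tone epochs.  When no background
    epochs are given, every post-calibration epoch counts as background.
    """
    rec, _ = render_scene(scene_spec)
    cal = apply_calibration(rec, fit_calibration(rec, cal_window))
    spg = spectrogram(cal)
    if background_epochs is None:
        background_epochs = range(int(cal_window[1]), len(spg.epochs))
    bg = fit_background(spg, background_epochs)
    idx = list(range(int(cal_window[1]), len(spg.epochs)))
    sub = Spectrogram(epochs=tuple(spg.epochs[i] for i in idx),
                      times_s=np.asarray(spg.times_s)[idx])
    return spg, bg, sub
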