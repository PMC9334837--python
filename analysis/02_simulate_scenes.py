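#!/usr/bin/env python
"""Render the three canonical synthetic scenes and archive their truth.

Writes 16-bit WAVs plus truth JSON sidecars to scratch/scenes/ (audio is
bulky; everything downstream regenerates it from the seed instead of reading
these files) and a compact per-scene summary to results/scene_manifest.csv.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import pandas as pd

from ultrasurvey.fixtures import (forceps_scene, lights_scene,
                                  walkie_talkie_paired_scene)
from ultrasurvey.scenes import write_truth
from ultrasurvey.wav_io import write_wav

ROOT = Path(__file__).resolve().parents[1]
SCENES = ROOT / "scratch" / "scenes"
OUT = ROOT / "results"
SEED = 101


def main() -> None:
    SCENES.mkdir(parents=True, exist_ok=True)
    OUT.mkdir(exist_ok=True)
    rows = []

    for name, fx in (
        ("lights", lights_scene(seed=SEED)),
        ("lights_inside_ivc", lights_scene(seed=SEED,
                                           source_attenuation_db=30.0)),
        ("forceps_metal", forceps_scene(seed=SEED, condition="metal")),
        ("forceps_neoprene", forceps_scene(seed=SEED, condition="neoprene")),
        ("forceps_inside_ivc", forceps_scene(seed=SEED, condition="metal",
                                             enclosure_db=10.0)),
    ):
        rec = fx["recording"]
        write_wav(rec, SCENES / f"{name}.wav")
        write_truth(fx["truth"], SCENES / f"{name}.truth.json")
        rows.append({"scene": name, "duration_s": rec.duration_s,
                     "rate_hz": rec.rate_hz,
                     "n_sources": len(fx["truth"]["sources"]), "seed": SEED})
        print(f"rendered {name}: {rec.duration_s:.0f} s at "
              f"{rec.rate_hz:.0f} Hz, {len(fx['truth']['sources'])} sources")

    wk = walkie_talkie_paired_scene(seed=SEED)
    for dev in ("a", "b"):
        write_wav(wk[f"recording_{dev}"], SCENES / f"walkie_device_{dev}.wav")
    write_truth(wk["truth"], SCENES / "walkie.truth.json")
    rows.append({"scene": "walkie_paired",
                 "duration_s": wk["recording_a"].duration_s,
                 "rate_hz": wk["recording_a"].rate_hz,
                 "n_sources": len(wk["truth"]["sources"]), "seed": SEED})
    print("rendered walkie_paired: devices A (RF-susceptible) and B (MEMS)")

    pd.DataFrame(rows).to_csv(OUT / "scene_manifest.csv", index=False)
    print(f"wrote {OUT / 'scene_manifest.csv'}; audio under {SCENES}")


if __name__ == "__main__":
    main()
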