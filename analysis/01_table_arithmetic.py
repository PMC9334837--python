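#!/usr/bin/env python
"""Recompute the forceps-impact survey tables from their printed inputs.

The published table reports, for each standard band, the background level,
the measured impact level, their difference, and (metal vs neoprene) the
reduction achieved by a neoprene mat.  Here every derived cell is recomputed
from the background/measured columns alone and compared with the published
figure at printed precision.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import pandas as pd

import ultrasurvey.survey_data as sd
from ultrasurvey.band_metrics import (attenuation_estimate, difference_table,
                                      reduction_table)

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    metal = difference_table(sd.FORCEPS_METAL_BG, sd.FORCEPS_METAL_MEASURED)
    neo = difference_table(sd.FORCEPS_NEOPRENE_BG, sd.FORCEPS_NEOPRENE_MEASURED)
    ivc = difference_table(sd.FORCEPS_IVC_BG, sd.FORCEPS_IVC_MEASURED)
    metal = reduction_table(metal, neo)

    rows = []
    for cond, table in (("metal", metal), ("neoprene", neo), ("ivc", ivc)):
        for band in table.bands:
            recomputed = round(float(table[band]["difference_db_spl"]), 2)
            published = sd.PUBLISHED_DIFFERENCES[cond][band]
            rows.append({"table": cond, "band": band, "cell": "difference",
                         "recomputed_db": recomputed,
                         "published_db": published,
                         "match": recomputed == published})
    for band in metal.bands:
        recomputed = round(float(metal[band]["reduction_db_spl"]), 2)
        published = sd.PUBLISHED_REDUCTIONS[band]
        rows.append({"table": "metal-vs-neoprene", "band": band,
                     "cell": "reduction", "recomputed_db": recomputed,
                     "published_db": published,
                     "match": recomputed == published})
    frame = pd.DataFrame(rows)

    OUT.mkdir(exist_ok=True)
    frame.to_csv(OUT / "table1_reproduction.csv", index=False)

    n_ok = int(frame["match"].sum())
    print(f"{n_ok}/{len(frame)} derived cells reproduce at printed precision")
    att = attenuation_estimate(
        difference_table(sd.FORCEPS_METAL_BG, sd.FORCEPS_METAL_MEASURED), ivc)
    print("enclosure attenuation implied by the printed measured columns:")
    print(att.round(2).to_string())
    print(f"wrote {OUT / 'table1_reproduction.csv'}")


if __name__ == "__main__":
    main()
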