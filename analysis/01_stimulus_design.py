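#!/usr/bin/env python
"""Masker geometry and level design for both species.

Computes the brick-wall band edges of the 1/8-oct and 1-oct maskers, the
notched-noise flanking bands, and the level offset that equalises masker
energy within a species-appropriate auditory filter (Glasberg-Moore ERB),
then verifies the synthesised waveforms hit their RMS calibration.

Writes results/stimulus_design.csv.
"""

import numpy as np
import pandas as pd

from cortone.auditory_filter import glasberg_moore_erb
from cortone.stimgen import (
    BandSpec,
    NotchSpec,
    band_edges,
    equalize_masker_level,
    make_band_noise,
)

RESULTS = "results/stimulus_design.csv"

rows = []
for species, fc, narrow_level in [("human", 4000.0, 60.0), ("cat", 8000.0, 65.0)]:
    erb = glasberg_moore_erb(fc)
    narrow = BandSpec(fc, 1 / 8, narrow_level)
    wide = BandSpec(fc, 1.0, narrow_level)
    offset = equalize_masker_level(narrow, wide, erb)
    for name, spec in [("1/8-oct", narrow), ("1-oct", wide)]:
        sig = make_band_noise(spec, 1.0, 48_000.0, seed=0)
        rows.append({
            "species": species, "masker": name,
            "f_lo_hz": round(spec.f_lo_hz), "f_hi_hz": round(spec.f_hi_hz),
            "erb_hz": round(erb, 1),
            "level_db_spl": spec.level_db_spl if name == "1/8-oct"
            else round(spec.level_db_spl + offset, 1),
            "equalization_offset_db": round(offset, 2),
            "measured_rms_db": round(sig.rms_db_spl, 2),
        })
    for df in (0.1, 0.2, 0.3):
        (lo1, hi1), (lo2, hi2) = NotchSpec(fc, df, 0.0).bands()
        rows.append({
            "species": species, "masker": f"notch {df:.0%}",
            "f_lo_hz": round(lo1), "f_hi_hz": round(hi2),
            "erb_hz": round(erb, 1), "level_db_spl": np.nan,
            "equalization_offset_db": np.nan, "measured_rms_db": np.nan,
        })

table = pd.DataFrame(rows)
table.to_csv(RESULTS, index=False)
print(table.to_string(index=False))
print(f"\nEqualization: the 1-oct masker needs "
      f"+{table.loc[table.species.eq('human'), 'equalization_offset_db'].iloc[0]:.1f} dB "
      f"(human, 456-Hz ERB) and "
      f"+{table.loc[table.species.eq('cat'), 'equalization_offset_db'].iloc[0]:.1f} dB "
      f"(cat bands, 888-Hz human ERB) to match the 1/8-oct masker's "
      f"filter-passed energy.\nWrote {RESULTS}")
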