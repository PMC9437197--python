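#!/usr/bin/env python
"""End-to-end cortical-onset-response recovery on synthetic recordings.

Generates a default human session (5 probe frequencies x masker, 20 blocks
of 13-probe sweeps -> 240 analysable epochs per condition) with a known
masking pattern injected via the level-growth law, runs the full extraction
chain (montage, epoch, 1-20 Hz FIR, ocular rejection, baseline, N1/P2
picking) and compares recovered with injected masking.

Writes results/cor_masking_recovery.csv.
"""

import numpy as np
import pandas as pd

from cortone.cor_pipeline import HUMAN_CONFIG, run_pipeline, to_db_re_unmasked
from cortone.synthetic_data import HUMAN_EEG_SPEC, gen_eeg_session

RESULTS = "results/cor_masking_recovery.csv"
SEED = 20_220

# stimulus-level masking (dB) per probe frequency: strong at the masker
# centre, relaxing toward the band edges, as for a 1/8-oct masker
grid = {2828.0: 10.0, 3364.0: 35.0, 4000.0: 60.0, 4757.0: 35.0, 5657.0: 10.0}
conds = [{"label": "no-masker", "probe_level_db": 70.0, "masking_db": 0.0}]
conds += [{"label": f"{f:.0f}Hz", "probe_level_db": 70.0, "masking_db": m}
          for f, m in grid.items()]

recs, truth = gen_eeg_session(HUMAN_EEG_SPEC, conds, n_blocks=20, seed=SEED)
truth = truth.set_index("label")
results = {lab: run_pipeline(rec, HUMAN_CONFIG) for lab, rec in recs.items()}
ref = results["no-masker"]

rows = []
for f, m in grid.items():
    lab = f"{f:.0f}Hz"
    r = results[lab]
    got = to_db_re_unmasked(r.amplitude_uv, ref.amplitude_uv)
    inj = 20 * np.log10(truth.loc[lab, "true_amplitude_uv"]
                        / truth.loc["no-masker", "true_amplitude_uv"])
    rows.append({
        "probe_freq_hz": f,
        "n_epochs_used": r.n_epochs_used,
        "amplitude_uv": round(r.amplitude_uv, 2),
        "true_amplitude_uv": round(truth.loc[lab, "true_amplitude_uv"], 2),
        "recovered_masking_db": round(got, 2),
        "injected_masking_db": round(inj, 2),
        "error_db": round(got - inj, 2),
    })

table = pd.DataFrame(rows)
table.to_csv(RESULTS, index=False)
print(table.to_string(index=False))
print(f"\nUnmasked COR: {ref.amplitude_uv:.2f} uV from {ref.n_epochs_used} epochs "
      f"(injected {truth.loc['no-masker', 'true_amplitude_uv']:.2f} uV).")
print(f"Mean |error| across the masked grid: "
      f"{table.error_db.abs().mean():.2f} dB.\nWrote {RESULTS}")
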