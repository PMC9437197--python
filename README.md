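# cortone

Tools for measuring **tonotopic selectivity** — how sharply the auditory
system separates sound frequencies — from two kinds of evidence collected
with the same masking stimuli:

* the **cortical onset response (COR)**: a scalp-recorded evoked potential to
  the onset of a 50-ms tone probe presented against a continuous noise
  masker, quantified as the P1−N1 (cat) or P2−N1 (human) peak-to-peak
  amplitude; and
* **masked detection thresholds** from behavioural tasks: a go/no-go
  hold-release paradigm (animals) and a 2AFC 2-down 1-up adaptive staircase
  (humans).

The package implements the full analysis chain for both measures and the
models that connect them, and ships a synthetic-data module so that every
stage can be exercised against known ground truth.

## What is inside

| module | contents |
|---|---|
| `cortone.stimgen` | band-limited, notched and pink-noise maskers (frequency-domain synthesis with brick-wall edges), ramped tone probes, ERB-based masker-level equalization |
| `cortone.auditory_filter` | roex(p) filter `W(g) = (1+pg)e^{-pg}` with ERB `= 4fc/p`, the power-spectrum model of masking, least-squares notched-noise fitting, subject bootstrap, the Glasberg–Moore ERB curve |
| `cortone.cor_pipeline` | montage differencing, epoching, zero-phase FIR bandpass, artifact flagging (4×RMS / ocular z > 4), averaging with baseline, peak picking, dB re unmasked |
| `cortone.psychophysics` | hold-release trial scoring with catch-trial (weighted) false-alarm rates, `d' = z(P_hit) − z(P_FA)`, `P(c)max = Φ(d'/2)`, logistic thresholds at P(c)max = 0.69, permutation chance ceiling, 2-down 1-up staircases |
| `cortone.level_growth` | shared-slope COR-vs-level growth model and the conversion of COR masking (dB re unmasked) into equivalent threshold shifts (divide by the slope) |
| `cortone.excitation_sim` | a simplified level-dependent roex excitation-pattern array used to study upward spread of excitation |
| `cortone.synthetic_data` | seed-deterministic generators: EEG sessions with injected onset complexes, hold-release sessions from logistic observers with impatience, notched-noise thresholds from known filters |

The numbered scripts under `analysis/` run the pipeline end to end on
synthetic data and write tables under `results/`.

## Worked example

Fit an auditory filter to notched-noise thresholds with a known answer:

```python
from cortone.auditory_filter import fit_roex, bootstrap_erb
from cortone.synthetic_data import gen_notch_thresholds

data, truth = gen_notch_thresholds(
    true_erb_hz=477.0, fc_hz=4000.0, efficiency_k_db=1.0,
    noise_sd_db=1.0, n_subjects=11, seed=777, masker_level_db=67.9)
fit = fit_roex(data)
mean, sd = bootstrap_erb(data, n_boot=10_000, seed=778)
print(f"ERB {fit.erb_hat_hz:.1f} Hz (bootstrap {mean:.1f} ± {sd:.1f} Hz)")
```

prints

```
ERB 478.4 Hz (bootstrap 478.5 ± 3.8 Hz)
```

i.e. with 1-dB threshold noise across 11 subjects the equivalent rectangular
bandwidth of the 4-kHz filter is recovered within ~0.3 % of the generating
value, and the subject bootstrap puts a few hertz of sampling error on it.
Running `python analysis/02_cor_masking_recovery.py` similarly rebuilds a
240-epoch-per-condition synthetic EEG session and recovers the injected
masking pattern with a mean absolute error of ~0.5 dB; the other numbered
scripts cover stimulus design, behavioural scoring and the COR-to-threshold
conversion.

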