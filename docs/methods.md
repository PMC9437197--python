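# Methods

This note documents the models, the defaults and the design choices behind
`cortone`, and what the synthetic-data generators do and do not emulate.

## Stimuli

Maskers are synthesised in the frequency domain: a flat magnitude spectrum
between brick-wall cut-offs (amplitude ∝ 1/√f for pink noise), phases drawn
uniformly from (−π, π], DC and Nyquist bins zeroed, inverse real FFT.  A
band of width *w* octaves geometrically centred on *f_c* spans
*f_c*·2^(−w/2) … *f_c*·2^(+w/2).  Notched maskers are built from the
1-octave band split at the centre: each half keeps its width in Hz while the
inner edges move to *f_c*(1 ∓ Δf), so Δf = 0 reproduces the 1-octave band
exactly and the total masker power is independent of notch width.

Calibration is purely digital: samples are pressures in Pa and a signal's
RMS level in dB SPL (re 20 µPa) is set exactly at synthesis; no transducer
or free-field transfer functions are modelled.  Tone probes default to
50 ms; the raised-cosine ramp `sin²(πt/2T)` covers both the "cosine-squared"
(cat, 5 ms) and "sine-squared" (human, 2 ms) conventions, which name the
same function.

`equalize_masker_level` equates the power two maskers pass through a
*rectangular* filter of ERB width centred on the shared centre frequency: a
band narrower than the ERB passes fully.  For the human bands at 4 kHz with
a 456-Hz ERB this gives +7.93 dB for the 1-octave masker; for the cat bands
at 8 kHz with the 888-Hz human ERB it gives +8.04 dB, i.e. a 1-octave level
of 73.0 dB SPL against the 65-dB narrowband masker.  (A published pilot
level of 73.2 dB SPL for this configuration does not follow from the
rectangular rule; the integration behind that figure is not specified, so
the package reports the rectangular-ERB value.)

## Auditory filter and the power-spectrum model

The filter is the single-parameter rounded exponential,
W(g) = (1 + pg)·e^(−pg) with g = |f − f_c|/f_c, whose equivalent rectangular
bandwidth is 4·f_c/p.  Band integrals use the closed form
∫W dg = [(2+pg₁)e^(−pg₁) − (2+pg₂)e^(−pg₂)]/p, verified against adaptive
quadrature to 1e−8 relative.

Detection threshold for a tone at f_c in a masker of spectrum level N₀
(dB/Hz) follows the power-spectrum model:
threshold = K + 10·log₁₀(f_c · Σ_bands ∫W dg · 10^(N₀/10)), with K the
listener-efficiency constant.  Fitting minimises squared dB error over
(p, K); K is profiled out in closed form and p is searched on an 80-point
log grid over [2, 200] and refined by bounded scalar minimisation, ties
broken toward smaller p (broader filters).  Only the symmetric single-p
filter is fitted — no roex(p, r) tail, no off-frequency listening — and the
fit is to cohort-mean thresholds; the ERB's sampling error comes from a
subject-resampling bootstrap (default 10,000 resamples, refitting the mean
of each resample).  Predicted thresholds can optionally be floored at a
quiet threshold by the caller; the fitter itself does not apply a floor.

## COR extraction

One code path serves both species through a `RecordingConfig`:

* **cat** — active-minus-reference montage, 3–20 Hz, analysis window
  0–120 ms, no baseline correction (only the post-onset window is analysed),
  artifact rule: an epoch whose peak magnitude within 0–120 ms exceeds 4×
  the RMS background (median per-epoch RMS — a robust background estimate,
  since the rule must not be dragged by the artifacts it hunts) is flagged;
  peaks P1 (15–55 ms) and N1 (55–120 ms) are the first slope reversal of the
  right polarity, after a 2-ms boxcar smoothing of the derivative's sign
  (the discretisation of "slope reversal" is otherwise ill-defined);
  amplitude = P1 − N1.
* **human** — contralateral-mastoid-minus-vertex montage (P7−Cz for
  right-ear stimulation, P8−Cz for left), 1–20 Hz FIR with 1-Hz transition
  and 2-s reflection padding, epochs −200…600 ms, −200…0 ms baseline,
  artifact rule: the above-minus-below-eye difference is z-scored over the
  whole recording and epochs containing |z| > 4 are flagged; N1 is the
  window minimum in 50–150 ms, P2 the maximum in 100–200 ms; amplitude =
  P2 − N1.

The bandpass is a Hamming-window FIR (odd length ≈ 3.3·rate/transition)
applied as a centred convolution, hence zero-phase; > 50 dB attenuation one
transition width beyond the edges.  Rejection is pure flagging — surviving
epochs are bit-identical — so the pipeline is invariant to epoch order.
Masked responses are expressed as 20·log₁₀(masked/unmasked) amplitude, the
scale on which they are compared with psychophysical threshold shifts.
Sweeps carry 13 probes at 1-s onset asynchrony; the first probe of each
sweep coincides with the masker onset and is dropped, so 20 blocks yield
240 analysable epochs per condition.  Recordings are read from a plain
matrix container (channels × samples with rate, channel names and trigger
times); EDF import is not implemented.

## Behavioural scoring

Release latencies partition exactly: early < −1000 ms ≤ false alarm < 0 ms
≤ hit ≤ 1000 ms < miss (the half-open boundaries are a documented choice;
the verbal windows "1000 to 0 ms prior" and "0 to 1000 ms after" leave
membership open).  Because a Hold N+1 trial's false-alarm window coincides
with a Hold N trial's hit window, hold-3/4/5 false-alarm rates serve as
catch-trial rates for holds 2/3/4 and are averaged with weights equal to
the tested hold-2/3/4 counts; hold-5 hits are never counted.  Sensitivity
is d' = z(P_hit) − z(P_FA) — both terms z-transformed, as required for
P(c)max = Φ(d'/2) to be the bias-free maximum proportion correct —
with proportions of 0 or 1 clipped to 1/(2N).  Thresholds interpolate a
logistic (lower asymptote fixed at chance 0.5, upper at 1.0) at
P(c)max = 0.69, the d' = 1 point.

The chance ceiling comes from a permutation test: each release is
re-expressed as a time from trial start, releases are shuffled across
trials while holds stay put (equivalent to shuffling the hold labels), the
session is rescored and the 95th percentile of the permuted P(c)max taken.
Under an exchangeable null — release times i.i.d. regardless of hold — the
test is exactly calibrated (≈5 % of null sessions exceed the ceiling).
Under a hold-dependent impatience hazard the recorded release support
differs between holds, permutation mixes the supports, and the test becomes
conservative; the synthetic-data module provides both nulls.

Staircases are 2-down 1-up: level down after two consecutive correct
responses, up after each incorrect, the correct-counter resetting on every
level change (the standard Levitt transform); 6-dB steps until two
turnpoints, 2-dB after; a run ends at 8 turnpoints and its threshold is the
mean of the last 6.  Sessions average 2 runs, adding a third when the first
two differ by more than 5 dB.  Simulated against a logistic observer the
track converges on the ~70.7 %-correct level (the asymptotic 2-down 1-up
point); the residual upward bias of the 8-turnpoint rule is under one
percentage point of the psychometric function.

## Level growth and the COR→threshold conversion

Unmasked COR amplitude (dB re 1 µV) is modelled as
COR = x·level + a_subject (+ b_subject·log₁₀(freq)), a shared-slope least
squares fit with subject-percentile-bootstrap CIs on x.  The subject
intercepts a_s are always estimated (with a single frequency the optional
per-subject frequency term is collinear with them and is disabled).  The
full mixed-effects machinery is deliberately replaced by this two-stage
fit: the quantity of interest is the single shared slope, and subject
resampling gives honest uncertainty at cohort sizes of 4–12.  Masked COR
reductions convert to equivalent threshold shifts as |ΔCOR|/x, with a
sensitivity sweep over the slope's confidence limits (defaults 0.13, 0.16,
0.19 dB/dB).  Growth of the COR *in the presence of a masker* is not
modelled.

## Excitation surrogate

`excitation_sim` is an explicit surrogate for a compressive nonlinear
filterbank, not a reimplementation of one: a tonotopic array of roex
channels (2 per ERB, 500–16,000 Hz) in which, after a linear first pass
estimates each channel's input level L, the lower-side steepness is scaled
by max(0.1, 1 − c·(L − 51)/50) (default c = 0.3; c = 0 is exactly the
linear symmetric model).  Rising level therefore broadens the low-frequency
skirt and produces upward spread of excitation.  The surrogate is validated
only qualitatively: at +10 dB probe-to-masker SNR the upper-edge probe of a
1-octave masker recruits more above-masker channels (with-probe excitation
exceeding masker-alone by > 1 dB, above a 0-dB audibility floor) than the
centred or lower-edge probes.  No quantitative match to any physiological
filterbank is claimed.  `predicted_masking` — filtered masker power at the
probe's best channel minus a detection offset — is a bookkeeping rule used
only to inject known masking into synthetic sessions.

One known residual: equalizing the 1/8- and 1-octave maskers with the
rectangular-ERB rule and passing both through a *roex* filter leaves
~0.8 dB more 1-octave power (~1.4 dB at the nearest quantized channel),
because the narrow band is not fully passed by the roex skirts; the tests
pin this residual to its quadrature value rather than asserting exact
equality.

## Synthetic data

The EEG generator emulates: an onset complex (sums of Gaussian bumps —
human N1 −4 µV/100 ms, P2 +3 µV/180 ms; cat P1 +2 µV/30 ms, N1 −3 µV/80 ms,
all inside their species peak windows) injected at the signal electrode,
scaled per condition by the growth law at the effective level
(probe level − injected masking, slope 0.16 dB/dB human / 0.34 cat);
1/f-power background noise (amplitude ∝ 1/√f down to 0.5 Hz, flat below;
8 µV RMS per channel) of which 80 % of the power is a source shared across
channels — scalp backgrounds are strongly correlated between electrodes, so
a bipolar montage must not double the noise; sweep timing with a jittered
inter-sweep gap (1.2 s plus up to 0.2 s of per-sweep computing time), which
also prevents stimulus-rate harmonics of the background from surviving the
epoch average coherently; and optional artifacts (human: ~80 µV ocular
deflections, opposite polarity above/below the eye, bleeding weakly into
the scalp leads; cat: 60-µV spikes inside the analysis window).  It does
not emulate: alpha rhythms or other narrowband EEG structure, drifting
electrode impedances, latency jitter of the evoked complex, or any
dependence of the response shape (rather than amplitude) on condition —
so recovery tests demonstrate the pipeline's correctness under realistic
noise levels, not its robustness to every failure mode of real recordings.

Behavioural sessions come from a logistic detector (midpoint, slope, lapse)
whose spontaneous-release probability grows per second of holding
(q_k = q₀·impatience^k), reproducing the empirical increase of false alarms
and lucky hits with hold time; its ground-truth threshold is computed
analytically as the level where the expected P(c)max of the full scoring
chain crosses 0.69.  Notched-noise thresholds are power-spectrum-model
predictions from a known roex filter plus per-subject Gaussian noise.

All generators are deterministic given a seed and emit machine-readable
truth tables.

## Problem sizes and numerical defaults

Synthetic EEG runs at 256 Hz — ample for 1–20 Hz signals and two orders
cheaper than acquisition rates; tests synthesise audio at 32 kHz while
presets carry 48/97.7 kHz.  End-to-end COR recovery is summarised as the
mean absolute error over a five-condition masked grid (single-condition
errors at 240 epochs have ~1 dB spread; the grid mean is the session-level
quantity of interest).  Bootstrap defaults: 10,000 resamples for ERBs,
1,000 for growth slopes; the permutation ceiling uses ≥ 1,000 shuffles.
Degenerate inputs fail loudly: under-determined fits, single-subject
bootstraps, unsorted triggers, all-rejected epochs, non-positive
amplitudes in dB conversions, empty spectra.

## Known limitations

* The roex fit assumes symmetric filters and on-frequency listening; real
  filters are asymmetric, so fitted ERBs blend both skirts.
* The excitation surrogate's level-dependence rule is phenomenological;
  only orderings, not magnitudes, should be read from it.
* The permutation ceiling is conservative under hold-dependent response
  hazards (see above).
* The analysis assumes recordings are already band-limited and properly
  triggered; no acquisition-side modelling is attempted.
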