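"""Synthetic ground-truth fixtures for every stage of the analysis.

Three generators, all seed-deterministic and all emitting a machine-readable
truth table next to their data:

* `gen_eeg_session` — multichannel scalp recordings with a known onset
  complex injected at the mastoid channel.  The complex's amplitude follows
  a level-growth law (dB of COR per dB of effective probe level) and a
  per-condition masking law (explicit dB, or the excitation-array rule), on
  top of 1/f background noise and optional ocular/spike artifacts.
* `gen_holdrelease_session` — go/no-go pedal sessions from a logistic
  psychometric observer whose spontaneous-release (impatience) hazard grows
  with hold time, mirroring the structure of real animal sessions.
* `gen_notch_thresholds` — notched-noise detection thresholds from a known
  roex(p) filter via the power-spectrum model, plus per-subject Gaussian
  measurement noise.

Defaults follow the study structure: 13-probe sweeps at 1-s onset asynchrony
repeated over 20 blocks (240 analysable epochs per condition after dropping
the masker-coincident first probe), holds of 2-5 s, notch widths of 0-30 %
of the centre frequency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .auditory_filter import NotchThresholdData, RoexFilter, predict_notch_threshold
from .cor_pipeline import Recording
from .stimgen import band_edges

__all__ = [
    "PeakSpec",
    "SyntheticEEGSpec",
    "HUMAN_EEG_SPEC",
    "CAT_EEG_SPEC",
    "gen_eeg_session",
    "SyntheticObserver",
    "gen_holdrelease_session",
    "gen_notch_thresholds",
    "notch_masker_density_db",
]


# ---------------------------------------------------------------------------
# EEG sessions


@dataclass(frozen=True)
class PeakSpec:
    latency_ms: float
    amplitude_uv: float
    width_ms: float  # Gaussian sigma


@dataclass
class SyntheticEEGSpec:
    species: str
    peaks: tuple
    growth_slope_db_per_db: float
    reference_level_db: float          # probe level at which peaks have nominal size
    noise_rms_uv: float = 8.0
    shared_noise_frac: float = 0.8     # fraction of noise power common to all channels
    artifact_rate: float = 0.0
    rate_hz: float = 256.0
    sweep_len: int = 13
    soa_s: float = 1.0
    gap_s: float = 1.2
    gap_jitter_s: float = 0.2          # uniform extra inter-sweep computing time
    lead_in_s: float = 1.0


HUMAN_EEG_SPEC = SyntheticEEGSpec(
    species="human",
    peaks=(PeakSpec(100.0, -4.0, 18.0), PeakSpec(180.0, 3.0, 22.0)),
    growth_slope_db_per_db=0.16,
    reference_level_db=70.0,
)

CAT_EEG_SPEC = SyntheticEEGSpec(
    species="cat",
    peaks=(PeakSpec(30.0, 2.0, 7.0), PeakSpec(80.0, -3.0, 12.0)),
    growth_slope_db_per_db=0.34,
    reference_level_db=75.0,
)


def _one_over_f_noise(n: int, rate_hz: float, rms_uv: float,
                      rng: np.random.Generator, f_floor_hz: float = 0.5) -> np.ndarray:
    """1/f-power noise: amplitude ~ 1/sqrt(f) down to f_floor, flat below."""
    freqs = np.fft.rfftfreq(n, 1.0 / rate_hz)
    mag = np.zeros_like(freqs)
    mag[1:] = 1.0 / np.sqrt(np.maximum(freqs[1:], f_floor_hz))
    phases = rng.uniform(-np.pi, np.pi, size=freqs.size)
    x = np.fft.irfft(mag * np.exp(1j * phases), n=n)
    return x * (rms_uv / np.sqrt(np.mean(x ** 2)))


def _template(spec: SyntheticEEGSpec, scale: float, n: int, rate_hz: float) -> np.ndarray:
    """Onset complex as a sum of Gaussian bumps, scaled by the growth law."""
    t_ms = np.arange(n) / rate_hz * 1000.0
    w = np.zeros(n)
    for pk in spec.peaks:
        w += pk.amplitude_uv * np.exp(-0.5 * ((t_ms - pk.latency_ms) / pk.width_ms) ** 2)
    return scale * w


def template_amplitude_uv(spec: SyntheticEEGSpec) -> float:
    """Nominal peak-to-peak amplitude of the injected complex (uV)."""
    n = int(0.6 * spec.rate_hz)
    w = _template(spec, 1.0, n, spec.rate_hz)
    return float(w.max() - w.min())


def growth_scale(spec: SyntheticEEGSpec, effective_level_db: float) -> float:
    """Amplitude factor from the growth law, relative to the reference level."""
    d_db = spec.growth_slope_db_per_db * (effective_level_db - spec.reference_level_db)
    return 10.0 ** (d_db / 20.0)


def gen_eeg_session(spec: SyntheticEEGSpec, conditions: list[dict],
                    n_blocks: int = 20, seed: int | np.random.Generator = 0):
    """One synthetic recording per condition, plus a truth table.

    Each condition dict needs: label, probe_level_db and masking_db (dB of
    injected COR reduction, >= 0).  The injected complex rides on the
    species' signal channel (human: P7; cat: active); the per-condition true
    amplitude is the template scaled by the growth law at the effective
    level probe_level - masking_db.

    Returns (recordings, truth): dict label -> Recording and a DataFrame
    with the injected amplitudes and masking per condition.
    """
    rng = np.random.default_rng(seed)
    sweep_s = spec.sweep_len * spec.soa_s + spec.gap_s
    dur_s = spec.lead_in_s + n_blocks * (sweep_s + spec.gap_jitter_s) + 2.0
    n = int(round(dur_s * spec.rate_hz))
    if spec.species == "human":
        ch_names = ["P7", "P8", "Cz", "EOG_above", "EOG_below"]
        signal_ch = "P7"
    else:
        ch_names = ["active", "reference"]
        signal_ch = "active"

    base_amp = template_amplitude_uv(spec)
    n_tpl = int(0.6 * spec.rate_hz)
    recordings, rows = {}, []
    for cond in conditions:
        masking = float(cond.get("masking_db", 0.0))
        eff = cond["probe_level_db"] - masking
        scale = growth_scale(spec, eff)
        tpl = _template(spec, scale, n_tpl, spec.rate_hz)

        # background: a source shared across the scalp plus channel-specific
        # noise, so a bipolar montage does not double the background power
        shared_rms = spec.noise_rms_uv * math.sqrt(spec.shared_noise_frac)
        indiv_rms = spec.noise_rms_uv * math.sqrt(1.0 - spec.shared_noise_frac)
        shared = _one_over_f_noise(n, spec.rate_hz, shared_rms, rng)
        data = np.stack([
            shared + _one_over_f_noise(n, spec.rate_hz, indiv_rms, rng)
            for _ in ch_names
        ])
        triggers = []
        t0 = spec.lead_in_s
        for _ in range(n_blocks):
            triggers.extend(t0 + k * spec.soa_s for k in range(spec.sweep_len))
            # inter-sweep gap varies with per-sweep computing time, which also
            # decorrelates stimulus-rate-harmonic noise across sweeps
            t0 += sweep_s + rng.uniform(0.0, spec.gap_jitter_s)
        triggers = np.array(triggers)
        sig = data[ch_names.index(signal_ch)]
        for t in triggers:
            i0 = int(round(t * spec.rate_hz))
            sig[i0:i0 + n_tpl] += tpl[: max(0, min(n_tpl, n - i0))]

        if spec.artifact_rate > 0:
            art_mask = rng.random(triggers.size) < spec.artifact_rate
            for t in triggers[art_mask]:
                i0 = int(round(t * spec.rate_hz))
                if spec.species == "human":
                    # ocular deflection: ~300 ms half-sine, opposite sign
                    # above/below the eye, small bleed into the scalp leads
                    n_a = int(0.3 * spec.rate_hz)
                    art = 80.0 * np.sin(np.pi * np.arange(n_a) / n_a)
                    sl = slice(i0, min(i0 + n_a, n))
                    m = sl.stop - sl.start
                    data[ch_names.index("EOG_above"), sl] += art[:m]
                    data[ch_names.index("EOG_below"), sl] -= art[:m]
                    data[ch_names.index("P7"), sl] += 0.3 * art[:m]
                    data[ch_names.index("Cz"), sl] += 0.1 * art[:m]
                else:
                    # myogenic spike inside the analysis window
                    i_spk = i0 + int(0.05 * spec.rate_hz)
                    n_a = max(2, int(0.01 * spec.rate_hz))
                    data[ch_names.index("active"), i_spk:i_spk + n_a] += 60.0

        rec = Recording(data, spec.rate_hz, list(ch_names), triggers,
                        meta={"condition": cond["label"], "species": spec.species})
        recordings[cond["label"]] = rec
        rows.append({
            "label": cond["label"],
            "probe_level_db": cond["probe_level_db"],
            "masking_db": masking,
            "true_amplitude_uv": base_amp * scale,
        })
    truth = pd.DataFrame(rows)
    return recordings, truth


# ---------------------------------------------------------------------------
# Hold-release behavioural sessions


@dataclass
class SyntheticObserver:
    """Logistic detector with hold-time-dependent impatience.

    p_detect(L) = (1 - lapse) / (1 + exp(-(L - midpoint)/slope)).  In each
    1-s window k of the hold (k = 0, 1, ...), the observer spontaneously
    releases with probability q_k = min(q0 * impatience^k, 0.9), so false
    alarms and lucky hits grow with hold time.
    """

    midpoint_db: float
    slope_db: float = 2.0
    lapse: float = 0.0
    q0: float = 0.02
    impatience: float = 1.4
    holds: tuple = (2, 3, 4, 5)

    def p_detect(self, level_db: float) -> float:
        return (1.0 - self.lapse) / (1.0 + math.exp(-(level_db - self.midpoint_db) / self.slope_db))

    def q(self, k: int) -> float:
        return min(self.q0 * self.impatience ** k, 0.9)

    # -- analytic session statistics -------------------------------------
    def _window_probs(self, hold: int):
        """(P(early), P(fa), P(reach probe)) for one hold time."""
        p_survive = 1.0
        p_early = 0.0
        for k in range(hold - 1):
            p_early += p_survive * self.q(k)
            p_survive *= 1.0 - self.q(k)
        p_fa = p_survive * self.q(hold - 1)
        p_reach = p_survive * (1.0 - self.q(hold - 1))
        return p_early, p_fa, p_reach

    def expected_pcmax(self, level_db: float) -> float:
        """P(c)max the scoring chain converges to at this probe level."""
        pd_ = self.p_detect(level_db)
        # pooled hit rate over holds 2-4 (reached trials only)
        p_hit = pd_ + (1.0 - pd_) * np.mean([self.q(h) for h in (2, 3, 4)])
        # weighted FA: hold-h FA rate among scored, h = 3, 4, 5
        rates, weights = [], []
        for h in (3, 4, 5):
            p_early, p_fa, _ = self._window_probs(h)
            rates.append(p_fa / (1.0 - p_early))
            weights.append(1.0)  # holds tested uniformly
        p_fa_w = float(np.average(rates, weights=weights))
        p_hit = min(max(p_hit, 1e-6), 1 - 1e-6)
        p_fa_w = min(max(p_fa_w, 1e-6), 1 - 1e-6)
        d = stats.norm.ppf(p_hit) - stats.norm.ppf(p_fa_w)
        return float(stats.norm.cdf(d / 2.0))

    def true_threshold(self, criterion: float = 0.69) -> float:
        """Level at which the expected P(c)max crosses the criterion (d'=1)."""
        f = lambda L: self.expected_pcmax(L) - criterion  # noqa: E731
        lo = self.midpoint_db - 30.0
        hi = self.midpoint_db + 30.0
        return float(optimize.brentq(f, lo, hi))


def gen_holdrelease_session(observer: SyntheticObserver, probe_levels_db,
                            n_trials_per_level: int = 40,
                            probe_freq_hz: float = 8000.0, masker: str = "1/8-oct",
                            seed: int | np.random.Generator = 0) -> tuple[pd.DataFrame, dict]:
    """Simulate a hold-release session; returns (trial log, truth dict).

    Trial log columns: session, hold_s, release_ms_re_probe (NaN = none),
    masker, probe_freq_hz, probe_level_db.  Truth holds the observer's
    parameters and its d' = 1 threshold.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for level in np.atleast_1d(probe_levels_db):
        for _ in range(n_trials_per_level):
            hold = int(rng.choice(observer.holds))
            release = math.nan
            # pre-probe spontaneous releases, second by second
            for k in range(hold):
                if rng.random() < observer.q(k):
                    t = k + rng.random()          # s from trial start
                    release = (t - hold) * 1000.0
                    break
            if math.isnan(release):
                if rng.random() < observer.p_detect(level):
                    release = rng.uniform(150.0, 900.0)   # detection latency
                elif rng.random() < observer.q(hold):
                    release = rng.uniform(0.0, 1000.0)    # lucky guess
            rows.append({"session": 0, "hold_s": hold,
                         "release_ms_re_probe": release, "masker": masker,
                         "probe_freq_hz": probe_freq_hz,
                         "probe_level_db": float(level)})
    truth = {
        "midpoint_db": observer.midpoint_db,
        "slope_db": observer.slope_db,
        "threshold_db_dprime1": observer.true_threshold(),
    }
    return pd.DataFrame(rows), truth


def gen_null_holdrelease_session(n_trials: int = 160,
                                 seed: int | np.random.Generator = 0,
                                 no_release_rate: float = 0.3,
                                 max_release_s: float = 7.0) -> pd.DataFrame:
    """Exchangeable null session: release times independent of probe onset.

    Release times (from trial start) are i.i.d. uniform on [0, max_release_s]
    regardless of the hold, with a fixed no-release probability, so the hold
    labels and releases are exactly exchangeable.  This is the null for which
    the permutation chance test is exactly calibrated; hold-dependent
    impatience hazards (see `SyntheticObserver`) make the test conservative.
    """
    rng = np.random.default_rng(seed)
    holds = rng.choice((2, 3, 4, 5), n_trials).astype(float)
    t = rng.uniform(0.0, max_release_s, n_trials)
    t[rng.random(n_trials) < no_release_rate] = np.nan
    return pd.DataFrame({
        "session": 0,
        "hold_s": holds.astype(int),
        "release_ms_re_probe": (t - holds) * 1000.0,
        "masker": "none",
        "probe_freq_hz": 8000.0,
        "probe_level_db": -200.0,
    })


# ---------------------------------------------------------------------------
# Notched-noise thresholds


def notch_masker_density_db(masker_level_db: float, fc_hz: float) -> float:
    """Spectrum level (dB/Hz) of the fixed-width notched masker.

    The two flanking bands jointly span the 1-octave bandwidth regardless of
    notch width, so the density is level - 10 log10(octave bandwidth).
    """
    f_lo, f_hi = band_edges(fc_hz, 1.0)
    return masker_level_db - 10.0 * math.log10(f_hi - f_lo)


def gen_notch_thresholds(true_erb_hz: float, fc_hz: float, efficiency_k_db: float,
                         noise_sd_db: float, n_subjects: int,
                         seed: int | np.random.Generator = 0,
                         delta_f_fracs=(0.0, 0.1, 0.2, 0.3),
                         masker_level_db: float = 67.9) -> tuple[NotchThresholdData, dict]:
    """Thresholds from a known roex filter + per-subject Gaussian noise."""
    if true_erb_hz <= 0 or fc_hz <= 0 or noise_sd_db < 0 or n_subjects < 1:
        raise ValueError("parameters must be positive (noise_sd >= 0)")
    from .auditory_filter import bands_for_notch

    rng = np.random.default_rng(seed)
    p_true = 4.0 * fc_hz / true_erb_hz
    filt = RoexFilter(p_true, fc_hz)
    density = notch_masker_density_db(masker_level_db, fc_hz)
    delta_f_fracs = np.asarray(delta_f_fracs, dtype=float)
    clean = np.array([
        predict_notch_threshold(filt, bands_for_notch(fc_hz, df), density,
                                efficiency_k_db)
        for df in delta_f_fracs
    ])
    thresholds = clean[None, :] + rng.normal(0.0, noise_sd_db,
                                             size=(n_subjects, delta_f_fracs.size))
    data = NotchThresholdData(fc_hz, delta_f_fracs, thresholds, density)
    truth = {"erb_hz": true_erb_hz, "p": p_true, "efficiency_k_db": efficiency_k_db,
             "clean_thresholds_db": clean}
    return data, truth
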