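"""Cortical onset response (COR) extraction from triggered scalp recordings.

A single config-driven chain serves both species: derive a single channel
from the montage, cut epochs around probe triggers, zero-phase FIR bandpass,
flag artifact epochs, average (with optional baseline correction), pick the
onset-complex peaks, and express masked amplitudes in dB re the unmasked
condition.  The cat preset quantifies P1 - N1 (slope-reversal peak picking in
15-55 / 55-120 ms windows, 3-20 Hz); the human preset quantifies P2 - N1
(window extrema in 100-200 / 50-150 ms, 1-20 Hz, -200..0 ms baseline,
contralateral-mastoid-minus-vertex montage).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "Recording",
    "RecordingConfig",
    "EpochSet",
    "CORResult",
    "CAT_CONFIG",
    "HUMAN_CONFIG",
    "derive_channel",
    "epoch",
    "bandpass",
    "reject_artifacts",
    "average_and_baseline",
    "pick_peaks",
    "to_db_re_unmasked",
    "run_pipeline",
]


@dataclass
class Recording:
    """Raw matrix container: channels x samples plus a minimal header."""

    data: np.ndarray           # (n_channels, n_samples), microvolts
    rate_hz: float
    ch_names: list[str]
    trigger_times_s: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.trigger_times_s = np.asarray(self.trigger_times_s, dtype=float)
        if self.data.shape[0] != len(self.ch_names):
            raise ValueError("ch_names must match the number of data rows")

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.data[self.ch_names.index(name)]
        except ValueError:
            raise KeyError(f"channel {name!r} not in recording") from None


@dataclass(frozen=True)
class RecordingConfig:
    species: str
    filter_band_hz: tuple[float, float]
    filter_transition_hz: float
    pad_s: float
    epoch_window_ms: tuple[float, float]
    baseline_window_ms: tuple[float, float] | None
    peak_windows_ms: dict          # label -> (lo, hi); order = extraction order
    peak_polarity: dict            # label -> +1 / -1
    peak_method: str               # 'slope-reversal' | 'extremum'
    montage: str                   # 'contra-mastoid-minus-vertex' | 'active-minus-reference'
    artifact_rule: str             # 'rms-4x' | 'eog-z4'
    amplitude_pair: tuple[str, str]  # (positive peak, negative peak)
    artifact_window_ms: tuple[float, float] | None = None
    smooth_ms: float = 2.0         # boxcar width for slope-reversal picking

    def __post_init__(self):
        for lo, hi in self.peak_windows_ms.values():
            if not (self.epoch_window_ms[0] <= lo < hi <= self.epoch_window_ms[1]):
                raise ValueError("peak windows must lie inside the epoch window")


CAT_CONFIG = RecordingConfig(
    species="cat",
    filter_band_hz=(3.0, 20.0),
    filter_transition_hz=1.0,
    pad_s=2.0,
    epoch_window_ms=(0.0, 120.0),
    baseline_window_ms=None,
    peak_windows_ms={"P1": (15.0, 55.0), "N1": (55.0, 120.0)},
    peak_polarity={"P1": +1, "N1": -1},
    peak_method="slope-reversal",
    montage="active-minus-reference",
    artifact_rule="rms-4x",
    artifact_window_ms=(0.0, 120.0),
    amplitude_pair=("P1", "N1"),
)

HUMAN_CONFIG = RecordingConfig(
    species="human",
    filter_band_hz=(1.0, 20.0),
    filter_transition_hz=1.0,
    pad_s=2.0,
    epoch_window_ms=(-200.0, 600.0),
    baseline_window_ms=(-200.0, 0.0),
    peak_windows_ms={"N1": (50.0, 150.0), "P2": (100.0, 200.0)},
    peak_polarity={"N1": -1, "P2": +1},
    peak_method="extremum",
    montage="contra-mastoid-minus-vertex",
    artifact_rule="eog-z4",
    amplitude_pair=("P2", "N1"),
)


@dataclass
class EpochSet:
    epochs: np.ndarray                 # (n_epochs, n_times), microvolts
    rate_hz: float
    t_ms: np.ndarray                   # time re probe onset
    rejected: np.ndarray = None        # bool mask
    reject_reason: list = None
    labels: dict = field(default_factory=dict)

    def __post_init__(self):
        self.epochs = np.atleast_2d(np.asarray(self.epochs, dtype=float))
        if self.rejected is None:
            self.rejected = np.zeros(self.epochs.shape[0], dtype=bool)
        if self.reject_reason is None:
            self.reject_reason = [None] * self.epochs.shape[0]

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_surviving(self) -> int:
        return int((~self.rejected).sum())

    def window_mask(self, lo_ms: float, hi_ms: float) -> np.ndarray:
        return (self.t_ms >= lo_ms) & (self.t_ms <= hi_ms)


@dataclass
class CORResult:
    peaks: dict                    # label -> (latency_ms or nan, amplitude_uv or nan)
    amplitude_uv: float            # positive-minus-negative peak; nan if absent
    n_epochs_used: int
    amplitude_db_re_unmasked: float | None = None


def derive_channel(rec: Recording, config: RecordingConfig,
                   stim_side: str = "right") -> np.ndarray:
    """Reduce the montage to one trace.

    Human: contralateral mastoid minus vertex (P7 - Cz for right-ear
    stimulation, P8 - Cz for left).  Cat: active minus reference.
    """
    if config.montage == "contra-mastoid-minus-vertex":
        mastoid = {"right": "P7", "left": "P8"}[stim_side]
        return rec.channel(mastoid) - rec.channel("Cz")
    if config.montage == "active-minus-reference":
        return rec.channel("active") - rec.channel("reference")
    raise ValueError(f"unknown montage {config.montage!r}")


def epoch(trace: np.ndarray, rate_hz: float, trigger_times_s: np.ndarray,
          window_ms: tuple[float, float], drop_first_per_sweep: bool = False,
          sweep_len: int = 13) -> EpochSet:
    """Cut epochs around probe triggers.

    With `drop_first_per_sweep`, every sweep_len-th trigger (the probe whose
    onset coincides with the masker onset) is discarded: 13-probe sweeps give
    12 analysable probes each.
    """
    triggers = np.asarray(trigger_times_s, dtype=float)
    if np.any(np.diff(triggers) < 0):
        raise ValueError("trigger times must be sorted")
    if drop_first_per_sweep:
        keep = np.arange(triggers.size) % sweep_len != 0
        triggers = triggers[keep]
    lo_ms, hi_ms = window_ms
    i_lo = int(round(lo_ms / 1000.0 * rate_hz))
    i_hi = int(round(hi_ms / 1000.0 * rate_hz))
    n_times = i_hi - i_lo
    onsets = np.round(triggers * rate_hz).astype(int)
    if np.any(onsets + i_lo < 0) or np.any(onsets + i_hi > trace.size):
        raise ValueError("epoch window extends beyond the recording")
    idx = onsets[:, None] + np.arange(i_lo, i_hi)[None, :]
    t_ms = np.arange(i_lo, i_hi) / rate_hz * 1000.0
    return EpochSet(trace[idx], rate_hz, t_ms)


def _fir_kernel(rate_hz: float, band_hz: tuple[float, float],
                transition_hz: float) -> np.ndarray:
    """Linear-phase bandpass FIR (Hamming); symmetric, hence zero-phase when
    applied centred.  Hamming windows give > 50 dB stopband attenuation one
    transition-width beyond the edges."""
    lo, hi = band_hz
    if rate_hz <= 2 * hi:
        raise ValueError("sampling rate too low for the filter's upper edge")
    numtaps = int(round(3.3 * rate_hz / transition_hz))
    numtaps += 1 - numtaps % 2  # odd length -> integer group delay
    return sps.firwin(numtaps, [lo, hi], pass_zero=False, fs=rate_hz,
                      window="hamming")


def bandpass(epochs: EpochSet, config: RecordingConfig) -> EpochSet:
    """Zero-phase FIR bandpass with edge padding.

    Each epoch is extended by `pad_s` of reflected signal on both sides before
    filtering so the FIR warm-up transient falls outside the epoch.
    """
    kernel = _fir_kernel(epochs.rate_hz, config.filter_band_hz,
                         config.filter_transition_hz)
    n_pad = int(round(config.pad_s * epochs.rate_hz))
    x = epochs.epochs
    n_pad_eff = min(n_pad, x.shape[1] - 1)
    padded = np.pad(x, ((0, 0), (n_pad_eff, n_pad_eff)), mode="reflect")
    filtered = sps.fftconvolve(padded, kernel[None, :], mode="same", axes=1)
    out = filtered[:, n_pad_eff:n_pad_eff + x.shape[1]]
    return EpochSet(out, epochs.rate_hz, epochs.t_ms, epochs.rejected.copy(),
                    list(epochs.reject_reason), dict(epochs.labels))


def reject_artifacts(epochs: EpochSet, config: RecordingConfig,
                     eog_trace: np.ndarray | None = None,
                     eog_epochs: np.ndarray | None = None) -> EpochSet:
    """Flag artifact epochs; surviving epochs are untouched (pure flagging).

    cat ('rms-4x'): an epoch is flagged when its peak magnitude within the
    analysis window exceeds 4x the RMS background level (median per-epoch RMS
    over the window, a robust background estimate).

    human ('eog-z4'): the above-minus-below-eye difference is z-scored over
    the whole recording; epochs containing |z| > 4 are flagged.  Pass the
    continuous EOG difference as `eog_trace` and the matching epoch index via
    `eog_epochs` (same shape as epochs.epochs, holding EOG samples).
    """
    out = EpochSet(epochs.epochs, epochs.rate_hz, epochs.t_ms,
                   epochs.rejected.copy(), list(epochs.reject_reason),
                   dict(epochs.labels))
    if config.artifact_rule == "rms-4x":
        lo, hi = config.artifact_window_ms
        m = out.window_mask(lo, hi)
        seg = out.epochs[:, m]
        rms_bg = float(np.median(np.sqrt(np.mean(seg ** 2, axis=1))))
        bad = np.max(np.abs(seg), axis=1) > 4.0 * rms_bg
        reason = "peak > 4x RMS background"
    elif config.artifact_rule == "eog-z4":
        if eog_trace is None or eog_epochs is None:
            raise ValueError("human artifact rule needs eog_trace and eog_epochs")
        mu, sd = float(np.mean(eog_trace)), float(np.std(eog_trace))
        z = (eog_epochs - mu) / sd
        bad = np.max(np.abs(z), axis=1) > 4.0
        reason = "EOG z-score > 4"
    else:
        raise ValueError(f"unknown artifact rule {config.artifact_rule!r}")
    for i in np.flatnonzero(bad & ~out.rejected):
        out.rejected[i] = True
        out.reject_reason[i] = reason
    return out


def average_and_baseline(epochs: EpochSet,
                         baseline_window_ms: tuple[float, float] | None) -> np.ndarray:
    """Mean over surviving epochs, minus the baseline-window mean if given."""
    keep = ~epochs.rejected
    if not keep.any():
        raise ValueError("all epochs rejected; nothing to average")
    mean = epochs.epochs[keep].mean(axis=0)
    if baseline_window_ms is not None:
        m = epochs.window_mask(*baseline_window_ms)
        mean = mean - mean[m].mean()
    return mean


def _slope_reversal(wave: np.ndarray, t_ms: np.ndarray, window: tuple[float, float],
                    polarity: int, rate_hz: float, smooth_ms: float) -> tuple[float, float]:
    """First slope reversal of the given polarity inside the window.

    polarity +1: rising-to-falling reversal (local maximum); -1: the converse.
    The waveform is lightly boxcar-smoothed before differencing; the reported
    amplitude is read from the unsmoothed waveform.
    """
    n_sm = max(1, int(round(smooth_ms / 1000.0 * rate_hz)))
    smoothed = np.convolve(wave, np.ones(n_sm) / n_sm, mode="same")
    d = np.sign(np.diff(smoothed))
    mask = (t_ms >= window[0]) & (t_ms <= window[1])
    idxs = np.flatnonzero(mask)
    for i in idxs:
        if 1 <= i < d.size:
            if polarity > 0 and d[i - 1] > 0 and d[i] <= 0:
                return float(t_ms[i]), float(wave[i])
            if polarity < 0 and d[i - 1] < 0 and d[i] >= 0:
                return float(t_ms[i]), float(wave[i])
    return float("nan"), float("nan")


def pick_peaks(mean_wave: np.ndarray, t_ms: np.ndarray, config: RecordingConfig,
               rate_hz: float, n_epochs_used: int = 0) -> CORResult:
    """Extract the onset-complex peaks and the peak-to-peak amplitude.

    Cat preset: first slope reversal of the required polarity inside each
    window.  Human preset: window extremum (global min for N1, max for P2).
    A flat window yields an absent peak and an undefined amplitude.
    """
    peaks = {}
    for label, window in config.peak_windows_ms.items():
        pol = config.peak_polarity[label]
        if config.peak_method == "slope-reversal":
            lat, amp = _slope_reversal(mean_wave, t_ms, window, pol, rate_hz,
                                       config.smooth_ms)
        else:
            m = (t_ms >= window[0]) & (t_ms <= window[1])
            seg, seg_t = mean_wave[m], t_ms[m]
            if seg.size == 0 or np.ptp(seg) == 0:
                lat, amp = float("nan"), float("nan")
            else:
                i = int(np.argmax(seg)) if pol > 0 else int(np.argmin(seg))
                lat, amp = float(seg_t[i]), float(seg[i])
        peaks[label] = (lat, amp)
    pos, neg = config.amplitude_pair
    amplitude = peaks[pos][1] - peaks[neg][1]
    return CORResult(peaks=peaks, amplitude_uv=float(amplitude),
                     n_epochs_used=n_epochs_used)


def to_db_re_unmasked(masked_amplitude_uv: float, unmasked_amplitude_uv: float) -> float:
    """Masked COR amplitude in dB re the unmasked amplitude (<= 0 for maskers)."""
    if not (masked_amplitude_uv > 0 and unmasked_amplitude_uv > 0):
        raise ValueError("amplitudes must be positive to express in dB")
    return 20.0 * np.log10(masked_amplitude_uv / unmasked_amplitude_uv)


def run_pipeline(rec: Recording, config: RecordingConfig, stim_side: str = "right",
                 drop_first_per_sweep: bool = True, sweep_len: int = 13) -> CORResult:
    """Full chain on one recording: derive, epoch, filter, reject, average, pick."""
    trace = derive_channel(rec, config, stim_side)
    eps = epoch(trace, rec.rate_hz, rec.trigger_times_s, config.epoch_window_ms,
                drop_first_per_sweep=drop_first_per_sweep, sweep_len=sweep_len)
    eps = bandpass(eps, config)
    if config.artifact_rule == "eog-z4":
        eog = rec.channel("EOG_above") - rec.channel("EOG_below")
        raw_eog = epoch(eog, rec.rate_hz, rec.trigger_times_s,
                        config.epoch_window_ms,
                        drop_first_per_sweep=drop_first_per_sweep,
                        sweep_len=sweep_len)
        eps = reject_artifacts(eps, config, eog_trace=eog,
                               eog_epochs=raw_eog.epochs)
    else:
        eps = reject_artifacts(eps, config)
    mean = average_and_baseline(eps, config.baseline_window_ms)
    return pick_peaks(mean, eps.t_ms, config, rec.rate_hz,
                      n_epochs_used=eps.n_surviving)
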