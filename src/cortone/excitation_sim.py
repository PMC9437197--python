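"""Simplified level-dependent excitation-pattern simulator.

A tonotopic array of roex(p) filters (2 channels per ERB by default) whose
lower-frequency slope optionally shallows as the channel's input level
rises — an explicit, documented surrogate for a nonlinear compressive
filterbank, validated only against qualitative upward-spread behaviour, not
against any physiological filterbank.  It also supplies the generative
masking law used by the synthetic-data module; that law is a bookkeeping
device, not a physiological model.

The level-dependence rule: after a linear first pass that estimates each
channel's input level L (dB SPL), the lower-side steepness is scaled by
max(0.1, 1 - c * (L - 51) / 50), with c = 0 giving the linear symmetric
array.  Rising L therefore broadens the low-frequency skirt, producing
upward spread of excitation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .auditory_filter import RoexFilter, band_integral, glasberg_moore_erb

__all__ = [
    "Stimulus",
    "ChannelArray",
    "excitation",
    "channels_above",
    "predicted_masking",
]


@dataclass
class Stimulus:
    """Spectral description: pure-tone lines plus flat noise bands.

    tones: list of (freq_hz, level_db_spl); bands: list of
    (f_lo_hz, f_hi_hz, level_db_spl) with the level being the band's overall
    RMS level (flat spectral density across the band).
    """

    tones: list = field(default_factory=list)
    bands: list = field(default_factory=list)

    def __post_init__(self):
        if not self.tones and not self.bands:
            raise ValueError("empty spectrum")

    def plus(self, other: "Stimulus") -> "Stimulus":
        return Stimulus(self.tones + other.tones, self.bands + other.bands)


@dataclass
class ChannelArray:
    """Log-spaced roex channel array; c is the level-dependence coefficient."""

    f_lo_hz: float = 500.0
    f_hi_hz: float = 16_000.0
    channels_per_erb: float = 2.0
    c: float = 0.3
    centres_hz: np.ndarray = None

    def __post_init__(self):
        if self.centres_hz is None:
            fcs = [float(self.f_lo_hz)]
            while fcs[-1] < self.f_hi_hz:
                fcs.append(fcs[-1] + glasberg_moore_erb(fcs[-1]) / self.channels_per_erb)
            self.centres_hz = np.array(fcs)
        if np.any(np.diff(self.centres_hz) <= 0):
            raise ValueError("channel centres must be strictly increasing")

    def p_of(self, fc: float) -> float:
        return 4.0 * fc / glasberg_moore_erb(fc)


def _channel_power(fc: float, p_lower: float, p_upper: float, stim: Stimulus) -> float:
    """Linear filtered power (20 uPa^2-referenced units) in one channel."""
    total = 0.0
    for f, level in stim.tones:
        g = abs(f - fc) / fc
        p = p_lower if f < fc else p_upper
        total += 10.0 ** (level / 10.0) * (1.0 + p * g) * np.exp(-p * g)
    for f_lo, f_hi, level in stim.bands:
        n0 = 10.0 ** (level / 10.0) / (f_hi - f_lo)
        # split the band at fc, fold onto g >= 0 with the side's own p
        if f_lo < fc:
            hi = min(f_hi, fc)
            total += fc * n0 * band_integral(p_lower, (fc - hi) / fc, (fc - f_lo) / fc)
        if f_hi > fc:
            lo = max(f_lo, fc)
            total += fc * n0 * band_integral(p_upper, (lo - fc) / fc, (f_hi - fc) / fc)
    return total


def excitation(stim: Stimulus, array: ChannelArray) -> np.ndarray:
    """Per-channel output level (dB) for the stimulus spectrum.

    Two passes: a linear symmetric pass estimates each channel's input level
    L; the second pass applies the documented lower-slope broadening rule
    p_lower = p * max(0.1, 1 - c*(L-51)/50).  With c = 0 the passes coincide
    and the array is exactly the linear symmetric roex model.
    """
    out = np.empty(array.centres_hz.size)
    for i, fc in enumerate(array.centres_hz):
        p = array.p_of(fc)
        power = _channel_power(fc, p, p, stim)
        if array.c != 0.0 and power > 0:
            level = 10.0 * np.log10(power)
            scale = max(0.1, 1.0 - array.c * (level - 51.0) / 50.0)
            power = _channel_power(fc, p * scale, p, stim)
        out[i] = 10.0 * np.log10(power) if power > 0 else -np.inf
    return out


def channels_above(pattern_with: np.ndarray, pattern_without: np.ndarray,
                   margin_db: float = 1.0, floor_db: float = 0.0) -> int:
    """Count of channels where adding the probe raises excitation > margin.

    Channels whose with-probe excitation sits below `floor_db` (inaudible)
    are ignored, so vanishing filter tails cannot register as spread.
    """
    above = (pattern_with - pattern_without > margin_db) & (pattern_with > floor_db)
    return int(np.sum(above))


def predicted_masking(probe_freq_hz: float, masker: Stimulus, array: ChannelArray,
                      detection_offset_db: float = 45.0) -> float:
    """Generative COR masking law (dB, >= 0): filtered masker power at the
    probe's best channel minus a detection offset.

    Silence gives 0 dB.  This is a clearly labelled non-physiological rule
    used to inject known masking into synthetic recordings; the offset sets
    how much filtered masker level translates into COR reduction.
    """
    if not masker.tones and not masker.bands:
        return 0.0
    i = int(np.argmin(np.abs(array.centres_hz - probe_freq_hz)))
    fc = float(array.centres_hz[i])
    p = array.p_of(fc)
    power = _channel_power(fc, p, p, masker)
    if power <= 0:
        return 0.0
    return max(0.0, 10.0 * float(np.log10(power)) - detection_offset_db)
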