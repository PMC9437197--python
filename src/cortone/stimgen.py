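"""Masker and probe synthesis for simultaneous-masking experiments.

All maskers are built in the frequency domain: a flat (or 1/f-power, for
pink noise) magnitude spectrum between brick-wall cut-offs, uniformly random
phases, inverse real FFT.  Levels are RMS-calibrated in the digital domain
against a declared full-scale -> dB SPL mapping (20 uPa reference); no
transducer transfer functions are modelled.

Band geometry is geometric: a band of width `w` octaves centred on `fc` has
edges fc * 2**(-w/2) and fc * 2**(+w/2).  Notched maskers keep the Hz-width
of each flanking band fixed (equal to the corresponding half of the 1-octave
band) as the notch widens, so the zero-notch condition is exactly the
1-octave masker.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "P_REF_PA",
    "BandSpec",
    "NotchSpec",
    "ProbeSpec",
    "SampledSignal",
    "band_edges",
    "make_band_noise",
    "make_pink_noise",
    "make_notched_noise",
    "make_tone_probe",
    "equalize_masker_level",
    "CAT_PRESET",
    "HUMAN_PRESET",
]

#: Reference pressure for dB SPL (Pa).  Sample values are pressures in Pa.
P_REF_PA = 20e-6


def _rms_to_db_spl(rms: float) -> float:
    return 20.0 * math.log10(rms / P_REF_PA)


def _db_spl_to_rms(level_db: float) -> float:
    return P_REF_PA * 10.0 ** (level_db / 20.0)


def band_edges(centre_hz: float, width_oct: float) -> tuple[float, float]:
    """Brick-wall cut-offs of a geometrically centred band.

    Parameters
    ----------
    centre_hz : geometric centre frequency (Hz), > 0.
    width_oct : bandwidth in octaves, >= 0 (0 gives a degenerate line).

    Returns
    -------
    (f_lo, f_hi) with f_lo = centre * 2**(-width/2), f_hi = centre * 2**(+width/2).
    """
    if centre_hz <= 0:
        raise ValueError("centre_hz must be positive")
    if width_oct < 0:
        raise ValueError("width_oct must be non-negative")
    return centre_hz * 2.0 ** (-width_oct / 2.0), centre_hz * 2.0 ** (width_oct / 2.0)


@dataclass(frozen=True)
class BandSpec:
    """A flat-spectrum noise band with brick-wall edges."""

    centre_hz: float
    width_oct: float
    level_db_spl: float

    def __post_init__(self):
        band_edges(self.centre_hz, self.width_oct)  # validates

    @property
    def f_lo_hz(self) -> float:
        return band_edges(self.centre_hz, self.width_oct)[0]

    @property
    def f_hi_hz(self) -> float:
        return band_edges(self.centre_hz, self.width_oct)[1]

    @property
    def bandwidth_hz(self) -> float:
        return self.f_hi_hz - self.f_lo_hz


@dataclass(frozen=True)
class NotchSpec:
    """Notched-noise masker: two flanking bands of fixed Hz-width.

    The 1-octave band centred on `centre_hz` is split at the centre; the two
    halves are shifted apart symmetrically so the inner edges sit at
    centre*(1 -/+ delta_f_frac), each half keeping its original width in Hz.
    delta_f_frac = 0 reproduces the 1-octave band exactly.
    """

    centre_hz: float
    delta_f_frac: float
    level_db_spl: float

    def __post_init__(self):
        if self.centre_hz <= 0:
            raise ValueError("centre_hz must be positive")
        if not 0 <= self.delta_f_frac < 0.5:
            raise ValueError("delta_f_frac must be in [0, 0.5)")
        if self.bands()[0][0] <= 0:
            raise ValueError("lower flanking band extends below 0 Hz")

    @property
    def lower_half_width_hz(self) -> float:
        return self.centre_hz * (1.0 - 2.0 ** -0.5)

    @property
    def upper_half_width_hz(self) -> float:
        return self.centre_hz * (2.0 ** 0.5 - 1.0)

    def bands(self) -> list[tuple[float, float]]:
        """[(f_lo, f_hi)] of the two flanking bands, in Hz."""
        fc, df = self.centre_hz, self.delta_f_frac
        lo_hi = fc * (1.0 - df)
        hi_lo = fc * (1.0 + df)
        return [
            (lo_hi - self.lower_half_width_hz, lo_hi),
            (hi_lo, hi_lo + self.upper_half_width_hz),
        ]


@dataclass(frozen=True)
class ProbeSpec:
    """Ramped tone-pip probe.

    ramp_shape is 'cosine-squared' (cat preset, 5 ms) or 'sine-squared'
    (human preset, 2 ms); both name the same raised-cosine ramp
    sin^2(pi t / (2 ramp)).
    """

    freq_hz: float
    level_db_spl: float
    duration_ms: float = 50.0
    ramp_ms: float = 5.0
    ramp_shape: str = "cosine-squared"

    def __post_init__(self):
        if self.freq_hz <= 0:
            raise ValueError("freq_hz must be positive")
        if self.ramp_ms < 0:
            raise ValueError("ramp_ms must be non-negative")
        if self.duration_ms <= 2 * self.ramp_ms:
            raise ValueError("duration must exceed twice the ramp time")
        if self.ramp_shape not in ("cosine-squared", "sine-squared"):
            raise ValueError(f"unknown ramp_shape {self.ramp_shape!r}")


@dataclass
class SampledSignal:
    """Pressure waveform (Pa, calibrated so RMS dB SPL re 20 uPa is exact)."""

    samples: np.ndarray
    rate_hz: float
    meta: dict = field(default_factory=dict)

    @property
    def rms_db_spl(self) -> float:
        return _rms_to_db_spl(float(np.sqrt(np.mean(self.samples ** 2))))

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate_hz


def _synth_from_magnitude(mag: np.ndarray, n: int, rate_hz: float,
                          level_db_spl: float, rng: np.random.Generator) -> np.ndarray:
    """IFFT of magnitude * random phase; DC and Nyquist zero; RMS-calibrated."""
    mag = mag.astype(float).copy()
    mag[0] = 0.0
    if n % 2 == 0:
        mag[-1] = 0.0
    phases = rng.uniform(-np.pi, np.pi, size=mag.size)
    spec = mag * np.exp(1j * phases)
    x = np.fft.irfft(spec, n=n)
    rms = np.sqrt(np.mean(x ** 2))
    if rms == 0:
        raise ValueError("empty spectrum: no energy in passband")
    return x * (_db_spl_to_rms(level_db_spl) / rms)


def _check_nyquist(f_hi: float, rate_hz: float) -> None:
    if rate_hz <= 2.0 * f_hi:
        raise ValueError(f"sampling rate {rate_hz} Hz violates Nyquist for {f_hi} Hz")


def make_band_noise(spec: BandSpec, duration_s: float, rate_hz: float,
                    seed: int | np.random.Generator) -> SampledSignal:
    """Flat-spectrum noise between brick-wall cut-offs, random phase."""
    _check_nyquist(spec.f_hi_hz, rate_hz)
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate_hz))
    freqs = np.fft.rfftfreq(n, 1.0 / rate_hz)
    mag = ((freqs >= spec.f_lo_hz) & (freqs <= spec.f_hi_hz)).astype(float)
    x = _synth_from_magnitude(mag, n, rate_hz, spec.level_db_spl, rng)
    return SampledSignal(x, rate_hz, meta={"spec": spec, "kind": "band_noise"})


def make_notched_noise(spec: NotchSpec, duration_s: float, rate_hz: float,
                       seed: int | np.random.Generator) -> SampledSignal:
    """Two fixed-width flanking bands around a spectral notch."""
    bands = spec.bands()
    _check_nyquist(bands[-1][1], rate_hz)
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate_hz))
    freqs = np.fft.rfftfreq(n, 1.0 / rate_hz)
    mag = np.zeros_like(freqs)
    for f_lo, f_hi in bands:
        mag[(freqs >= f_lo) & (freqs <= f_hi)] = 1.0
    x = _synth_from_magnitude(mag, n, rate_hz, spec.level_db_spl, rng)
    return SampledSignal(x, rate_hz, meta={"spec": spec, "kind": "notched_noise"})


def make_pink_noise(f_lo_hz: float, f_hi_hz: float, level_per_sixth_oct_db: float,
                    rate_hz: float, seed: int | np.random.Generator,
                    duration_s: float = 1.0) -> SampledSignal:
    """Band-limited pink noise (equal energy per octave) with brick-wall edges.

    Calibrated so the power in any 1/6-octave slice of the passband equals
    `level_per_sixth_oct_db` (dB SPL).
    """
    if not (0 < f_lo_hz < f_hi_hz):
        raise ValueError("need 0 < f_lo < f_hi")
    _check_nyquist(f_hi_hz, rate_hz)
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate_hz))
    freqs = np.fft.rfftfreq(n, 1.0 / rate_hz)
    mag = np.zeros_like(freqs)
    sel = (freqs >= f_lo_hz) & (freqs <= f_hi_hz)
    mag[sel] = 1.0 / np.sqrt(freqs[sel])  # power density ~ 1/f
    # Pink noise over [f_lo, f_hi]: power in a slice [a, b] is proportional to
    # ln(b/a); a 1/6-oct slice carries ln(2)/6 of each octave's power.
    frac_sixth = (math.log(2.0) / 6.0) / math.log(f_hi_hz / f_lo_hz)
    overall_db = level_per_sixth_oct_db - 10.0 * math.log10(frac_sixth)
    x = _synth_from_magnitude(mag, n, rate_hz, overall_db, rng)
    return SampledSignal(
        x, rate_hz,
        meta={"kind": "pink_noise", "f_lo_hz": f_lo_hz, "f_hi_hz": f_hi_hz,
              "level_per_sixth_oct_db": level_per_sixth_oct_db},
    )


def make_tone_probe(spec: ProbeSpec, rate_hz: float) -> SampledSignal:
    """Ramped tone pip whose steady-state RMS matches the spec level."""
    _check_nyquist(spec.freq_hz, rate_hz)
    n = int(round(spec.duration_ms / 1000.0 * rate_hz))
    t = np.arange(n) / rate_hz
    amp = math.sqrt(2.0) * _db_spl_to_rms(spec.level_db_spl)
    x = amp * np.sin(2.0 * np.pi * spec.freq_hz * t)
    n_ramp = int(round(spec.ramp_ms / 1000.0 * rate_hz))
    if n_ramp > 0:
        ramp = np.sin(np.pi * np.arange(n_ramp) / (2.0 * n_ramp)) ** 2
        x[:n_ramp] *= ramp
        x[-n_ramp:] *= ramp[::-1]
    return SampledSignal(x, rate_hz, meta={"spec": spec, "kind": "tone_probe"})


def _rect_filter_passed_fraction(f_lo: float, f_hi: float,
                                 centre_hz: float, erb_hz: float) -> float:
    """Fraction of a flat band's power passed by a rectangular ERB filter."""
    lo = max(f_lo, centre_hz - erb_hz / 2.0)
    hi = min(f_hi, centre_hz + erb_hz / 2.0)
    overlap = max(0.0, hi - lo)
    return overlap / (f_hi - f_lo)


def equalize_masker_level(narrow: BandSpec, wide: BandSpec, erb_hz: float) -> float:
    """Level offset (dB) to add to the wide masker so both bands pass equal
    power through a rectangular filter of width `erb_hz` on the shared centre.

    A band narrower than the ERB passes fully; the +7.9 dB human offset
    (1/8-oct vs 1-oct at 4 kHz, ERB 456 Hz) follows from this rule.
    """
    if not math.isclose(narrow.centre_hz, wide.centre_hz, rel_tol=1e-9):
        raise ValueError("bands must share a centre frequency")
    if erb_hz <= 0:
        raise ValueError("erb_hz must be positive")
    fc = narrow.centre_hz
    frac_n = _rect_filter_passed_fraction(narrow.f_lo_hz, narrow.f_hi_hz, fc, erb_hz)
    frac_w = _rect_filter_passed_fraction(wide.f_lo_hz, wide.f_hi_hz, fc, erb_hz)
    if frac_w == 0:
        raise ValueError("wide band passes no power through the filter")
    return 10.0 * math.log10(frac_n / frac_w)


#: Species stimulus presets: masker centre, probe ramp, default rate.
CAT_PRESET = {
    "masker_centre_hz": 8000.0,
    "probe_freqs_hz": [5657.0, 6727.0, 8000.0, 9514.0, 11314.0],
    "probe_level_db": 75.0,
    "narrow_level_db": 65.0,
    "ramp_ms": 5.0,
    "ramp_shape": "cosine-squared",
    "pink_band_hz": (85.0, 3700.0),
    "rate_hz": 97_700.0,
}
HUMAN_PRESET = {
    "masker_centre_hz": 4000.0,
    "probe_freqs_hz": [2828.0, 3364.0, 4000.0, 4757.0, 5657.0],
    "probe_level_db": 70.0,
    "narrow_level_db": 60.0,
    "ramp_ms": 2.0,
    "ramp_shape": "sine-squared",
    "pink_band_hz": (85.0, 1860.0),
    "rate_hz": 48_000.0,
}
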