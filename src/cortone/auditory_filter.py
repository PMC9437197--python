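"""Symmetric roex(p) auditory filter and the power-spectrum model of masking.

The filter weight is W(g) = (1 + p*g) * exp(-p*g), where g = |f - fc| / fc is
the normalised deviation from the centre frequency and p sets the steepness.
Its equivalent rectangular bandwidth is ERB = 4 * fc / p.  Detection threshold
for a tone at fc in a noise masker follows the power-spectrum model: the
threshold equals the filtered masker power plus a listener-efficiency constant
K (dB).  Fitting (p, K) to notched-noise thresholds yields the ERB; subject
bootstrap gives its sampling error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "RoexFilter",
    "NotchThresholdData",
    "FilterFit",
    "roex_weight",
    "band_integral",
    "glasberg_moore_erb",
    "erb_power_ratio",
    "predict_notch_threshold",
    "smr_at_filter_output",
    "fit_roex",
    "bootstrap_erb",
]


def roex_weight(g, p: float):
    """Rounded-exponential filter weight W(g) = (1 + p g) e^{-p g}.

    g must be >= 0 (the caller folds the two filter sides); p > 0.
    """
    g = np.asarray(g, dtype=float)
    if np.any(g < 0):
        raise ValueError("g must be non-negative (filter is symmetric)")
    if p <= 0:
        raise ValueError("p must be positive")
    out = (1.0 + p * g) * np.exp(-p * g)
    return out if out.ndim else float(out)


def band_integral(p: float, g1: float, g2: float) -> float:
    """Closed-form integral of W over [g1, g2] (g2 may be inf).

    integral W dg = [(2 + p g1) e^{-p g1} - (2 + p g2) e^{-p g2}] / p.
    The total area over (0, inf) is 2/p per side, i.e. ERB/fc = 4/p overall.
    """
    if p <= 0:
        raise ValueError("p must be positive")
    if g1 < 0 or g2 < g1:
        raise ValueError("need 0 <= g1 <= g2")

    def antider(g):
        if math.isinf(g):
            return 0.0
        return (2.0 + p * g) * math.exp(-p * g)

    return (antider(g1) - antider(g2)) / p


def glasberg_moore_erb(f_hz: float) -> float:
    """Human ERB (Hz) at centre frequency f: 24.7 * (4.37 * f_kHz + 1)."""
    if f_hz <= 0:
        raise ValueError("frequency must be positive")
    return 24.7 * (4.37 * f_hz / 1000.0 + 1.0)


def erb_power_ratio(erb_a_hz: float, erb_b_hz: float) -> float:
    """10 log10(erb_a / erb_b): extra broadband-noise power admitted by a."""
    if erb_a_hz <= 0 or erb_b_hz <= 0:
        raise ValueError("ERBs must be positive")
    return 10.0 * math.log10(erb_a_hz / erb_b_hz)


@dataclass(frozen=True)
class RoexFilter:
    p: float
    fc_hz: float

    def __post_init__(self):
        if self.p <= 0 or self.fc_hz <= 0:
            raise ValueError("p and fc_hz must be positive")

    @property
    def erb_hz(self) -> float:
        return 4.0 * self.fc_hz / self.p

    def weight(self, f_hz):
        g = np.abs(np.asarray(f_hz, dtype=float) - self.fc_hz) / self.fc_hz
        return roex_weight(g, self.p)

    def passed_band_area(self, f_lo: float, f_hi: float) -> float:
        """integral of W dg over a band [f_lo, f_hi] in Hz (split at fc)."""
        fc = self.fc_hz
        if f_hi <= f_lo:
            raise ValueError("need f_lo < f_hi")
        total = 0.0
        # below-fc portion
        if f_lo < fc:
            hi = min(f_hi, fc)
            total += band_integral(self.p, (fc - hi) / fc, (fc - f_lo) / fc)
        # above-fc portion
        if f_hi > fc:
            lo = max(f_lo, fc)
            total += band_integral(self.p, (lo - fc) / fc, (f_hi - fc) / fc)
        return total


def _filtered_masker_power_db(filt: RoexFilter, bands_hz, density_db_hz: float) -> float:
    """10 log10 of masker power at the filter output.

    bands_hz: iterable of (f_lo, f_hi) flat-spectrum bands, all at the same
    spectrum level density_db_hz (dB/Hz re 20 uPa^2-equivalent units).
    """
    bands_hz = list(bands_hz)
    if not bands_hz:
        raise ValueError("empty masker")
    area = sum(filt.passed_band_area(lo, hi) for lo, hi in bands_hz)
    if area <= 0:
        return -math.inf
    n0 = 10.0 ** (density_db_hz / 10.0)
    return 10.0 * math.log10(filt.fc_hz * area * n0)


def predict_notch_threshold(filt: RoexFilter, bands_hz, density_db_hz: float,
                            efficiency_k_db: float) -> float:
    """Power-spectrum-model threshold (dB SPL) for a tone at the filter centre.

    threshold = K + 10 log10(fc * sum_bands integral(W dg) * 10^(N0/10)).
    Monotone non-increasing in notch width; -inf when no masker power passes
    (an absolute-threshold floor, if any, is the caller's business).
    """
    return efficiency_k_db + _filtered_masker_power_db(filt, bands_hz, density_db_hz)


def smr_at_filter_output(probe_level_db: float, bands_hz, density_db_hz: float,
                         filt: RoexFilter) -> float:
    """Signal-to-masker ratio (dB) at the filter output for a tone at fc."""
    masker_db = _filtered_masker_power_db(filt, bands_hz, density_db_hz)
    if math.isinf(masker_db):
        raise ValueError("masker passes no power through the filter")
    return probe_level_db - masker_db


@dataclass
class NotchThresholdData:
    """Thresholds vs notch width for one cohort.

    thresholds_db_spl: array (n_subjects, n_notches) or (n_notches,) of
    detection thresholds; band geometry is rebuilt from fc and the
    fixed-width flanking-band rule via `bands_for_notch`.
    """

    fc_hz: float
    delta_f_fracs: np.ndarray
    thresholds_db_spl: np.ndarray
    masker_density_db: float

    def __post_init__(self):
        self.delta_f_fracs = np.asarray(self.delta_f_fracs, dtype=float)
        self.thresholds_db_spl = np.asarray(self.thresholds_db_spl, dtype=float)
        if len(np.unique(self.delta_f_fracs)) != self.delta_f_fracs.size:
            raise ValueError("delta_f values must be distinct")
        if np.any(self.delta_f_fracs < 0):
            raise ValueError("delta_f values must be >= 0")
        if not np.all(np.isfinite(self.thresholds_db_spl)):
            raise ValueError("thresholds must be finite")

    def mean_thresholds(self) -> np.ndarray:
        t = self.thresholds_db_spl
        return t if t.ndim == 1 else t.mean(axis=0)


def bands_for_notch(fc_hz: float, delta_f_frac: float) -> list[tuple[float, float]]:
    """Flanking-band geometry of the fixed-width notched-noise masker."""
    from .stimgen import NotchSpec

    return NotchSpec(fc_hz, delta_f_frac, level_db_spl=0.0).bands()


@dataclass
class FilterFit:
    p_hat: float
    erb_hat_hz: float
    efficiency_k_db: float
    converged: bool
    rss_db2: float
    erb_boot_mean_hz: float | None = None
    erb_boot_sd_hz: float | None = None
    n_boot: int = 0
    seed: int | None = None


def _notch_g_limits(fc_hz: float, delta_fs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(g1, g2) arrays, shape (n_notch, n_segments): flanking bands folded to g."""
    g1, g2 = [], []
    for df in delta_fs:
        segs = []
        for lo, hi in bands_for_notch(fc_hz, df):
            # flanking bands never straddle fc; fold onto g >= 0
            if hi <= fc_hz:
                segs.append(((fc_hz - hi) / fc_hz, (fc_hz - lo) / fc_hz))
            else:
                segs.append(((lo - fc_hz) / fc_hz, (hi - fc_hz) / fc_hz))
        g1.append([s[0] for s in segs])
        g2.append([s[1] for s in segs])
    return np.asarray(g1), np.asarray(g2)


def _areas(p, g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """Vectorized band_integral: sum over segments, broadcastable in p."""
    p = np.asarray(p, dtype=float)[..., None, None]
    a = lambda g: (2.0 + p * g) * np.exp(-p * g)  # noqa: E731
    return ((a(g1) - a(g2)) / p).sum(axis=-1)


def _fit_p_k(fc_hz: float, delta_fs: np.ndarray, thresholds: np.ndarray,
             density_db: float) -> tuple[float, float, float]:
    """Least squares over (p, K) in dB space.

    K is profiled out in closed form (it is an additive dB offset), p is
    searched on a log grid then refined; ties broken toward smaller p.
    """
    g1, g2 = _notch_g_limits(fc_hz, delta_fs)
    offset_db = 10.0 * math.log10(fc_hz) + density_db

    def rss_of(p) -> tuple[np.ndarray, np.ndarray]:
        pred0 = 10.0 * np.log10(_areas(p, g1, g2)) + offset_db
        k = np.mean(thresholds - pred0, axis=-1, keepdims=True)
        resid = thresholds - (pred0 + k)
        return (resid ** 2).sum(axis=-1), k[..., 0]

    grid = np.geomspace(2.0, 200.0, 80)
    rss_grid, _ = rss_of(grid)
    i = int(np.argmin(rss_grid))  # argmin takes the first (smallest-p) minimum
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    res = optimize.minimize_scalar(lambda p: float(rss_of(p)[0]), bounds=(lo, hi),
                                   method="bounded")
    p_hat = float(res.x)
    rss, k_hat = rss_of(p_hat)
    return p_hat, float(k_hat), float(rss)


def fit_roex(data: NotchThresholdData) -> FilterFit:
    """Fit a symmetric roex(p) filter to mean notched-noise thresholds.

    Requires >= 3 notch widths (two parameters p, K).  The fit is to the
    cohort mean; per-subject data are kept for bootstrapping.
    """
    if data.delta_f_fracs.size < 3:
        raise ValueError("need at least 3 notch widths to fit (p, K)")
    thresholds = data.mean_thresholds()
    p_hat, k_hat, rss = _fit_p_k(data.fc_hz, data.delta_f_fracs, thresholds,
                                 data.masker_density_db)
    converged = bool(np.isfinite(p_hat) and 2.0 < p_hat < 200.0)
    return FilterFit(
        p_hat=p_hat,
        erb_hat_hz=4.0 * data.fc_hz / p_hat,
        efficiency_k_db=k_hat,
        converged=converged,
        rss_db2=rss,
    )


def bootstrap_erb(data: NotchThresholdData, n_boot: int = 10_000,
                  seed: int | np.random.Generator = 0) -> tuple[float, float]:
    """Bootstrap ERB over subjects: resample rows, refit to resampled means.

    Returns (mean_hz, sd_hz); deterministic for a fixed seed.
    """
    t = data.thresholds_db_spl
    if t.ndim != 2 or t.shape[0] < 2:
        raise ValueError("bootstrap requires per-subject thresholds (>= 2 subjects)")
    rng = np.random.default_rng(seed)
    n_subj = t.shape[0]
    erbs = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n_subj, size=n_subj)
        mean_t = t[idx].mean(axis=0)
        p_hat, _, _ = _fit_p_k(data.fc_hz, data.delta_f_fracs, mean_t,
                               data.masker_density_db)
        erbs[b] = 4.0 * data.fc_hz / p_hat
    return float(erbs.mean()), float(erbs.std(ddof=1))
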