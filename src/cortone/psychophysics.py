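"""Signal-detection scoring of hold-release sessions and adaptive staircases.

The hold-release (go/no-go) task: the subject holds a pedal through a delay
drawn from {2, 3, 4, 5} s, then a probe starts; a release within 1 s after
probe onset is a hit.  Because the false-alarm window of a Hold N+1 trial
coincides exactly with the hit window of a Hold N trial, Hold N+1 false
alarms serve as catch trials for Hold N; Hold-5 hits are rewarded but not
scored.  Sensitivity is the equal-variance Gaussian index
d' = z(P_hit) - z(P_FA), summarised as the bias-free maximum proportion
correct P(c)max = Phi(d'/2); threshold is the level at which a logistic fit
of P(c)max vs level crosses 0.69 (d' = 1).  A permutation test that breaks
the association between hold times and pedal releases gives the chance
ceiling for P(c)max.

The 2AFC task is a 2-down 1-up staircase (6-dB steps until 2 turnpoints,
then 2 dB; threshold = mean of the last 6 of 8 turnpoints), which converges
on the 70.7 %-correct point of the psychometric function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "score_release",
    "score_trials",
    "weighted_false_alarm_rate",
    "hit_rate",
    "DetectionStats",
    "detection_stats",
    "session_pcmax",
    "PsychometricFit",
    "fit_threshold_pcmax",
    "permutation_chance",
    "LogisticObserver",
    "StaircaseResult",
    "run_staircase",
    "run_staircase_session",
]

HOLDS = (2, 3, 4, 5)
#: Release-latency scoring windows, ms re probe onset (half-open partition).
EARLY_BEFORE_MS = -1000.0
HIT_WINDOW_MS = (0.0, 1000.0)


def score_release(release_ms_re_probe: float | None) -> str:
    """Score one pedal release latency.

    early if < -1000 ms; false_alarm in [-1000, 0); hit in [0, 1000];
    miss if > 1000 ms or no release.
    """
    lat = release_ms_re_probe
    if lat is None or (isinstance(lat, float) and math.isnan(lat)):
        return "miss"
    if lat < EARLY_BEFORE_MS:
        return "early"
    if lat < HIT_WINDOW_MS[0]:
        return "false_alarm"
    if lat <= HIT_WINDOW_MS[1]:
        return "hit"
    return "miss"


def _score_array(lat_ms: np.ndarray) -> np.ndarray:
    """Vectorized scoring; NaN latency = no release = miss."""
    out = np.full(lat_ms.shape, "miss", dtype=object)
    has = ~np.isnan(lat_ms)
    out[has & (lat_ms < EARLY_BEFORE_MS)] = "early"
    out[has & (lat_ms >= EARLY_BEFORE_MS) & (lat_ms < 0)] = "false_alarm"
    out[has & (lat_ms >= 0) & (lat_ms <= HIT_WINDOW_MS[1])] = "hit"
    return out


def score_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Add a 'score' column; expects hold_s and release_ms_re_probe columns."""
    out = trials.copy()
    out["score"] = _score_array(out["release_ms_re_probe"].to_numpy(dtype=float))
    return out


def weighted_false_alarm_rate(trials: pd.DataFrame) -> float:
    """Catch-trial false-alarm rate for a session (one masker condition).

    Hold-h false-alarm rates (h = 3, 4, 5; false alarms among scored, i.e.
    non-early, hold-h trials) stand in for the hit windows of holds 2, 3, 4,
    and are averaged with weights equal to the distribution of tested holds
    2, 3 and 4.
    """
    t = trials if "score" in trials else score_trials(trials)
    scored = t[t["score"] != "early"]
    rates, weights = [], []
    for catch_hold in (3, 4, 5):
        g = scored[scored["hold_s"] == catch_hold]
        if len(g) == 0:
            continue
        rates.append((g["score"] == "false_alarm").mean())
        weights.append((scored["hold_s"] == catch_hold - 1).sum())
    if not rates or sum(weights) == 0:
        raise ValueError("no catch trials available (need holds 3-5 and tested holds 2-4)")
    return float(np.average(rates, weights=weights))


def hit_rate(trials: pd.DataFrame) -> tuple[float, int]:
    """(p_hit, n) among hold 2-4 trials that reached the hit window.

    Hold-5 trials are catch-only; false alarms and early releases never
    reached the probe and are excluded from the denominator.
    """
    t = trials if "score" in trials else score_trials(trials)
    g = t[t["hold_s"].isin((2, 3, 4)) & t["score"].isin(("hit", "miss"))]
    if len(g) == 0:
        raise ValueError("no scoreable hold 2-4 trials")
    return float((g["score"] == "hit").mean()), len(g)


def _clip_proportion(p: float, n: int | None) -> float:
    """Replace 0/1 by 1/(2N), 1 - 1/(2N) before the z-transform."""
    if 0.0 < p < 1.0:
        return p
    if n is None or n <= 0:
        raise ValueError("proportion of 0 or 1 needs a trial count to clip")
    return min(max(p, 1.0 / (2 * n)), 1.0 - 1.0 / (2 * n))


@dataclass(frozen=True)
class DetectionStats:
    p_hit: float
    p_false_alarm: float
    d_prime: float
    pcmax: float


def detection_stats(p_hit: float, p_fa: float, n_hit: int | None = None,
                    n_fa: int | None = None) -> DetectionStats:
    """d' = z(P_hit) - z(P_FA) and P(c)max = Phi(d'/2).

    Proportions at 0 or 1 are clipped to 1/(2N) from the boundary, which
    requires the corresponding trial count.
    """
    ph = _clip_proportion(float(p_hit), n_hit)
    pf = _clip_proportion(float(p_fa), n_fa)
    d = float(stats.norm.ppf(ph) - stats.norm.ppf(pf))
    return DetectionStats(ph, pf, d, float(stats.norm.cdf(d / 2.0)))


def session_pcmax(trials: pd.DataFrame) -> DetectionStats:
    """P(c)max for a set of trials: pooled hit rate vs weighted FA rate."""
    t = trials if "score" in trials else score_trials(trials)
    ph, n_h = hit_rate(t)
    pf = weighted_false_alarm_rate(t)
    scored = t[t["score"] != "early"]
    n_f = int(scored["hold_s"].isin((3, 4, 5)).sum())
    return detection_stats(ph, pf, n_hit=n_h, n_fa=n_f)


def _pcmax_rows(holds: np.ndarray, lat2d: np.ndarray) -> np.ndarray:
    """Vectorized session P(c)max for many latency assignments at once.

    holds: (n_trials,); lat2d: (n_rows, n_trials) release latencies (ms re
    probe, NaN = none).  Mirrors hit_rate / weighted_false_alarm_rate /
    detection_stats including the 1/(2N) clipping.
    """
    has = ~np.isnan(lat2d)
    early = has & (lat2d < EARLY_BEFORE_MS)
    fa = has & (lat2d >= EARLY_BEFORE_MS) & (lat2d < 0)
    hit = has & (lat2d >= 0) & (lat2d <= HIT_WINDOW_MS[1])
    scored = ~early
    in234 = np.isin(holds, (2, 3, 4))
    reached = scored & ~fa & in234  # hit or miss among holds 2-4
    n_hw = reached.sum(axis=1)
    p_hit = (hit & in234).sum(axis=1) / np.maximum(n_hw, 1)

    rate_sum = np.zeros(lat2d.shape[0])
    w_sum = np.zeros(lat2d.shape[0])
    for catch in (3, 4, 5):
        sel = scored & (holds == catch)
        n_sel = sel.sum(axis=1)
        w = (scored & (holds == catch - 1)).sum(axis=1)
        with np.errstate(invalid="ignore"):
            rate = (fa & (holds == catch)).sum(axis=1) / n_sel
        ok = n_sel > 0
        rate_sum += np.where(ok, rate * w, 0.0)
        w_sum += np.where(ok, w, 0)
    p_fa = rate_sum / np.maximum(w_sum, 1)
    n_fa = (scored & np.isin(holds, (3, 4, 5))).sum(axis=1)

    def clip(p, n):
        n = np.maximum(n, 1)
        return np.clip(p, 1.0 / (2 * n), 1.0 - 1.0 / (2 * n))

    d = stats.norm.ppf(clip(p_hit, n_hw)) - stats.norm.ppf(clip(p_fa, n_fa))
    return stats.norm.cdf(d / 2.0)


@dataclass
class PsychometricFit:
    threshold_db: float
    midpoint_db: float
    slope_db: float
    criterion: float
    converged: bool
    extrapolated: bool


def _logistic_pc(level, midpoint, slope):
    from scipy.special import expit

    return 0.5 + 0.5 * expit((np.asarray(level, dtype=float) - midpoint) / slope)


def fit_threshold_pcmax(levels_db, pcmax, criterion: float = 0.69,
                        n_trials=None) -> PsychometricFit:
    """Logistic fit of P(c)max vs level; threshold at the criterion crossing.

    The logistic has a fixed lower asymptote of 0.5 (chance) and upper
    asymptote 1.0; least squares over (midpoint, slope).  If the data do not
    bracket the criterion the threshold is an extrapolation and flagged.
    Monotone-decreasing data cannot be fitted (slope is bounded positive) and
    are flagged as non-converged.
    """
    levels = np.asarray(levels_db, dtype=float)
    pc = np.asarray(pcmax, dtype=float)
    if levels.size < 3:
        raise ValueError("need at least 3 levels")
    if not 0.5 < criterion < 1.0:
        raise ValueError("criterion must lie in (0.5, 1)")
    span = levels.max() - levels.min()
    try:
        (mid, slope), _ = optimize.curve_fit(
            _logistic_pc, levels, pc,
            p0=[float(np.median(levels)), max(span / 8.0, 0.5)],
            bounds=([levels.min() - 4 * span - 10.0, 1e-3],
                    [levels.max() + 4 * span + 10.0, 10 * span + 10.0]),
            maxfev=10_000,
        )
        converged = True
    except RuntimeError:
        mid, slope, converged = float("nan"), float("nan"), False
    if converged and np.corrcoef(levels, pc)[0, 1] < 0:
        converged = False  # decreasing data: the bounded fit is degenerate
    threshold = mid + slope * math.log((criterion - 0.5) / (1.0 - criterion)) \
        if converged else float("nan")
    extrapolated = bool(converged and not (pc.min() <= criterion <= pc.max()))
    return PsychometricFit(float(threshold), float(mid), float(slope),
                           criterion, converged, extrapolated)


def permutation_chance(trials: pd.DataFrame, n_perm: int = 1000,
                       seed: int | np.random.Generator = 0,
                       percentile: float = 95.0) -> float:
    """Chance ceiling for P(c)max by hold/release permutation.

    Each trial's pedal release is re-expressed as a time from trial start
    (hold + latency); releases (including "no release") are shuffled across
    trials while the hold times stay put, the session is rescored and
    P(c)max recomputed.  Returns the requested percentile of the permuted
    P(c)max distribution; deterministic for a fixed seed.
    """
    if n_perm < 1000:
        raise ValueError("need n_perm >= 1000 for a stable 95th percentile")
    holds = trials["hold_s"].to_numpy(dtype=float)
    lat = trials["release_ms_re_probe"].to_numpy(dtype=float)
    if holds.size < 10:
        raise ValueError("too few trials to permute")
    t_release = holds + lat / 1000.0  # seconds from trial start; NaN = none
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(holds.size) for _ in range(n_perm)])
    lat_perm = (t_release[perms] - holds[None, :]) * 1000.0
    vals = _pcmax_rows(holds, lat_perm)
    return float(np.percentile(vals, percentile))


@dataclass
class LogisticObserver:
    """2AFC observer: P(correct | level) = 0.5 + 0.5 / (1 + e^{-(L-m)/s})."""

    midpoint_db: float
    slope_db: float
    lapse: float = 0.0
    rng: np.random.Generator = field(default_factory=np.random.default_rng)

    def p_correct(self, level_db: float) -> float:
        pc = _logistic_pc(np.asarray(level_db, dtype=float),
                          self.midpoint_db, self.slope_db)
        return (1 - self.lapse) * pc + self.lapse * 0.5

    def respond(self, level_db: float) -> bool:
        return bool(self.rng.random() < self.p_correct(level_db))

    def level_at_pc(self, pc: float) -> float:
        """Level at which the (lapse-free) psychometric reaches pc."""
        if self.lapse:
            pc = (pc - 0.5 * self.lapse) / (1 - self.lapse)
        return self.midpoint_db + self.slope_db * math.log((pc - 0.5) / (1.0 - pc))


@dataclass
class StaircaseResult:
    threshold_db: float
    turnpoints_db: list
    track_db: list
    n_trials: int


def run_staircase(observer, start_level_db: float, step_big_db: float = 6.0,
                  step_small_db: float = 2.0, n_turnpoints: int = 8,
                  n_turnpoints_avg: int = 6, big_step_turnpoints: int = 2,
                  max_trials: int = 1000) -> StaircaseResult:
    """2-down 1-up adaptive track.

    Level decreases after two consecutive correct responses, increases after
    each incorrect one; the correct-counter resets on every level change.
    Steps are `step_big_db` until `big_step_turnpoints` turnpoints have
    occurred, then `step_small_db`; the run stops after `n_turnpoints`
    turnpoints and the threshold is the mean of the last `n_turnpoints_avg`.
    """
    level = float(start_level_db)
    track = [level]
    turnpoints: list[float] = []
    n_correct = 0
    direction = 0  # +1 up, -1 down, 0 before the first move
    for trial in range(max_trials):
        correct = observer.respond(level)
        move = 0
        if correct:
            n_correct += 1
            if n_correct >= 2:
                move = -1
        else:
            move = +1
        if move != 0:
            if direction != 0 and move != direction:
                turnpoints.append(level)
                if len(turnpoints) >= n_turnpoints:
                    break
            direction = move
            step = step_big_db if len(turnpoints) < big_step_turnpoints else step_small_db
            level += move * step
            n_correct = 0
            track.append(level)
    else:
        raise RuntimeError("staircase did not terminate within max_trials")
    threshold = float(np.mean(turnpoints[-n_turnpoints_avg:]))
    return StaircaseResult(threshold, turnpoints, track, trial + 1)


def run_staircase_session(observer, start_level_db: float,
                          max_run_difference_db: float = 5.0,
                          **kwargs) -> tuple[float, list[StaircaseResult]]:
    """Session rule: average 2 runs, adding a 3rd if they differ by > 5 dB."""
    runs = [run_staircase(observer, start_level_db, **kwargs) for _ in range(2)]
    if abs(runs[0].threshold_db - runs[1].threshold_db) > max_run_difference_db:
        runs.append(run_staircase(observer, start_level_db, **kwargs))
    return float(np.mean([r.threshold_db for r in runs])), runs
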