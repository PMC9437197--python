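"""Hold-release scoring, d'/P(c)max, thresholds, permutation test, staircases."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from cortone.psychophysics import (
    LogisticObserver,
    detection_stats,
    fit_threshold_pcmax,
    permutation_chance,
    run_staircase,
    run_staircase_session,
    score_release,
    score_trials,
    session_pcmax,
    weighted_false_alarm_rate,
)
from cortone.synthetic_data import (
    SyntheticObserver,
    gen_holdrelease_session,
    gen_null_holdrelease_session,
)


class TestScoring:
    @pytest.mark.parametrize(
        "lat, expected",
        [
            (-1200.0, "early"),
            (-500.0, "false_alarm"),
            (400.0, "hit"),
            (1500.0, "miss"),
            (None, "miss"),
            (0.0, "hit"),         # boundary: hit window is [0, 1000]
            (-1000.0, "false_alarm"),  # boundary: FA window is [-1000, 0)
            (1000.0, "hit"),
        ],
    )
    def test_release_windows(self, lat, expected):
        assert score_release(lat) == expected

    @given(st.floats(-5000, 5000, allow_nan=False))
    def test_scoring_is_a_partition(self, lat):
        assert score_release(lat) in {"early", "false_alarm", "hit", "miss"}

    def test_counts_reconcile(self, rng):
        lat = rng.uniform(-3000, 3000, 500)
        df = pd.DataFrame({"hold_s": rng.choice([2, 3, 4, 5], 500),
                           "release_ms_re_probe": lat})
        scored = score_trials(df)
        assert scored["score"].value_counts().sum() == 500


class TestWeightedFalseAlarm:
    def make_session(self, fa_rates, n_by_hold):
        """Exact per-hold FA proportions among scored trials.

        n_by_hold: counts for holds 2-5; hold-h trials that are not false
        alarms are misses.  The hold 2-4 counts double as the tested-hold
        weights for the hold 3-5 FA rates.
        """
        rows = [{"hold_s": 2, "release_ms_re_probe": 500.0}] * n_by_hold[0]
        for hold, r, n_h in zip((3, 4, 5), fa_rates, n_by_hold[1:]):
            n_fa = int(round(n_h * r))
            assert n_fa == n_h * r, "fixture requires exact counts"
            rows += [{"hold_s": hold, "release_ms_re_probe": -500.0}] * n_fa
            rows += [{"hold_s": hold, "release_ms_re_probe": np.nan}] * (n_h - n_fa)
        return pd.DataFrame(rows)

    def test_hand_computed_weighted_mean(self):
        # rates (0.1, 0.2, 0.3) weighted by tested holds 2-4 (0.5, 0.3, 0.2)
        df = self.make_session((0.1, 0.2, 0.3), (50, 30, 20, 40))
        assert weighted_false_alarm_rate(df) == pytest.approx(0.17, abs=1e-9)

    def test_equal_rates_pass_through(self):
        df = self.make_session((0.25, 0.25, 0.25), (40, 40, 20, 20))
        assert weighted_false_alarm_rate(df) == pytest.approx(0.25)

    def test_zero_false_alarms(self):
        df = self.make_session((0.0, 0.0, 0.0), (30, 30, 40, 20))
        assert weighted_false_alarm_rate(df) == 0.0

    def test_no_catch_trials(self):
        df = pd.DataFrame({"hold_s": [2, 2], "release_ms_re_probe": [500.0, 300.0]})
        with pytest.raises(ValueError):
            weighted_false_alarm_rate(df)


class TestDetectionStats:
    def test_dprime_one_gives_criterion_pcmax(self):
        # p_hit/p_fa chosen so z(ph) - z(pf) = 1 exactly
        s = detection_stats(stats.norm.cdf(0.5), stats.norm.cdf(-0.5))
        assert s.d_prime == pytest.approx(1.0, abs=1e-9)
        assert round(s.pcmax, 2) == 0.69

    def test_equal_rates_give_chance(self):
        s = detection_stats(0.3, 0.3)
        assert s.d_prime == 0.0
        assert s.pcmax == 0.5

    def test_normal_quantile_evaluation(self):
        s = detection_stats(0.84, 0.50)
        assert s.d_prime == pytest.approx(0.9945, abs=5e-4)

    def test_criterion_shift_invariance(self):
        # equal-variance observer: shifting the criterion changes both rates
        # but not d'
        d = 1.3
        for crit in (-0.5, 0.0, 0.8):
            s = detection_stats(stats.norm.cdf(d - crit), stats.norm.cdf(-crit))
            assert s.d_prime == pytest.approx(d, abs=1e-9)

    def test_boundary_proportions_need_counts(self):
        with pytest.raises(ValueError):
            detection_stats(1.0, 0.1)
        s = detection_stats(1.0, 0.1, n_hit=20)
        assert s.p_hit == 1 - 1 / 40


class TestThresholdFit:
    def test_noiseless_inversion(self):
        levels = np.arange(30.0, 51.0, 2.0)
        obs = LogisticObserver(40.0, 2.0)
        pc = [obs.p_correct(L) for L in levels]
        fit = fit_threshold_pcmax(levels, pc)
        assert fit.converged and not fit.extrapolated
        assert fit.threshold_db == pytest.approx(obs.level_at_pc(0.69), abs=0.5)

    def test_binomial_sampling_accuracy(self, rng):
        obs = LogisticObserver(40.0, 2.0)
        levels = np.arange(32.0, 49.0, 2.0)
        errs = []
        for _ in range(200):
            n = rng.integers(15, 31)
            pc = [rng.binomial(n, obs.p_correct(L)) / n for L in levels]
            fit = fit_threshold_pcmax(levels, pc)
            if fit.converged:
                errs.append(abs(fit.threshold_db - obs.level_at_pc(0.69)))
        assert np.median(errs) < 2.0

    def test_decreasing_data_flagged(self):
        levels = np.array([30.0, 35.0, 40.0, 45.0])
        fit = fit_threshold_pcmax(levels, [0.95, 0.8, 0.6, 0.5])
        assert not fit.converged

    def test_unbracketed_criterion_flagged(self):
        levels = np.array([30.0, 32.0, 34.0, 36.0])
        obs = LogisticObserver(50.0, 2.0)
        fit = fit_threshold_pcmax(levels, [obs.p_correct(L) for L in levels])
        assert fit.extrapolated


class TestPermutationChance:
    def test_seed_reproducibility(self):
        df = gen_null_holdrelease_session(120, seed=5)
        a = permutation_chance(df, n_perm=1000, seed=9)
        b = permutation_chance(df, n_perm=1000, seed=9)
        assert a == b

    def test_responsive_observer_beats_chance(self):
        obs = SyntheticObserver(midpoint_db=40.0, slope_db=1.0)
        df, _ = gen_holdrelease_session(obs, [55.0], 160, seed=11)
        ceiling = permutation_chance(df, n_perm=1000, seed=12)
        assert session_pcmax(df).pcmax > ceiling

    def test_null_observer_below_ceiling(self):
        df = gen_null_holdrelease_session(200, seed=13)
        ceiling = permutation_chance(df, n_perm=1000, seed=14)
        assert session_pcmax(df).pcmax < ceiling

    def test_too_few_permutations_rejected(self):
        df = gen_null_holdrelease_session(100, seed=1)
        with pytest.raises(ValueError):
            permutation_chance(df, n_perm=100, seed=1)


class _StepObserver:
    """Deterministic: always correct above the step level, never below."""

    def __init__(self, step_db):
        self.step_db = step_db

    def respond(self, level_db):
        return level_db >= self.step_db


class TestStaircase:
    def test_deterministic_observer_converges_to_step(self):
        res = run_staircase(_StepObserver(40.0), start_level_db=60.0)
        assert len(res.turnpoints_db) == 8
        assert abs(res.threshold_db - 40.0) <= 2.0  # within the small step

    def test_step_schedule(self):
        res = run_staircase(_StepObserver(40.0), start_level_db=60.0)
        # after the first two turnpoints all level moves are 2 dB
        track = np.asarray(res.track_db)
        late_steps = np.abs(np.diff(track))[-6:]
        assert np.all(late_steps == 2.0)

    def test_converges_to_70p7_percent_point(self):
        rng = np.random.default_rng(77)
        obs = LogisticObserver(40.0, 2.0, rng=rng)
        ths = [run_staircase(obs, 60.0).threshold_db for _ in range(3000)]
        target = obs.level_at_pc(0.707)
        assert np.mean(ths) == pytest.approx(target, abs=1.0)

    def test_third_run_triggered_on_disagreement(self):
        class DriftingObserver:
            """Deterministic step whose location jumps 6 dB between runs."""

            def __init__(self):
                self.step = 50.0
                self.prev_level = None

            def respond(self, level):
                # a fresh run is detectable by the level jumping back to start
                if level == 70.0 and self.prev_level != 70.0:
                    self.step = 80.0 - self.step  # alternate 50 <-> 30
                self.prev_level = level
                return level >= self.step

        mean, runs = run_staircase_session(DriftingObserver(), 70.0)
        assert len(runs) == 3  # first two runs differ by ~20 dB > 5 dB

        # agreeing runs stop at two
        mean2, runs2 = run_staircase_session(_StepObserver(40.0), 70.0)
        assert len(runs2) == 2

    def test_non_terminating_guard(self):
        class NeverCorrect:
            def respond(self, level):
                return False

        # 1-up only: no turnpoints ever, must hit the guard
        with pytest.raises(RuntimeError):
            run_staircase(NeverCorrect(), 40.0, max_trials=200)
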