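"""Evoked-response extraction: montage, epoching, filtering, rejection, peaks."""

import numpy as np
import pytest
from scipy import signal as sps

from cortone.cor_pipeline import (
    CAT_CONFIG,
    HUMAN_CONFIG,
    EpochSet,
    Recording,
    average_and_baseline,
    bandpass,
    derive_channel,
    epoch,
    pick_peaks,
    reject_artifacts,
    to_db_re_unmasked,
    run_pipeline,
)
from cortone.synthetic_data import HUMAN_EEG_SPEC, gen_eeg_session

RATE = 256.0


def make_recording(traces: dict, triggers, rate=RATE):
    names = list(traces)
    return Recording(np.stack([traces[n] for n in names]), rate, names,
                     np.asarray(triggers, dtype=float))


class TestDeriveChannel:
    def test_right_ear_uses_p7_minus_cz(self, rng):
        n = 1000
        p7, p8, cz = rng.normal(size=(3, n))
        rec = make_recording({"P7": p7, "P8": p8, "Cz": cz}, [1.0])
        out = derive_channel(rec, HUMAN_CONFIG, stim_side="right")
        assert np.array_equal(out, p7 - cz)
        out_l = derive_channel(rec, HUMAN_CONFIG, stim_side="left")
        assert np.array_equal(out_l, p8 - cz)

    def test_identical_channels_cancel(self, rng):
        x = rng.normal(size=500)
        rec = make_recording({"P7": x, "Cz": x.copy()}, [1.0])
        assert np.allclose(derive_channel(rec, HUMAN_CONFIG), 0.0)

    def test_mastoid_dipole_recovered_unchanged(self, rng):
        dipole = np.sin(np.linspace(0, 4 * np.pi, 800))
        rec = make_recording({"P7": dipole, "Cz": np.zeros(800)}, [1.0])
        assert np.array_equal(derive_channel(rec, HUMAN_CONFIG), dipole)

    def test_missing_channel(self):
        rec = make_recording({"P7": np.zeros(100)}, [0.2])
        with pytest.raises(KeyError):
            derive_channel(rec, HUMAN_CONFIG)


class TestEpoch:
    def trigger_grid(self, n_blocks=20, sweep_len=13):
        t = []
        for b in range(n_blocks):
            t.extend(2.0 + b * 15.0 + k * 1.0 for k in range(sweep_len))
        return np.array(t)

    def test_sweep_bookkeeping(self):
        trace = np.zeros(int(350 * RATE))
        trig = self.trigger_grid()
        eps = epoch(trace, RATE, trig, (-200.0, 600.0), drop_first_per_sweep=True)
        assert eps.n_epochs == 240
        eps_all = epoch(trace, RATE, trig, (-200.0, 600.0), drop_first_per_sweep=False)
        assert eps_all.n_epochs == 260

    def test_trigger_at_edge_rejected(self):
        with pytest.raises(ValueError):
            epoch(np.zeros(1000), RATE, [0.0], (-200.0, 600.0))

    def test_unsorted_triggers_rejected(self):
        with pytest.raises(ValueError):
            epoch(np.zeros(10000), RATE, [5.0, 2.0], (-200.0, 600.0))

    def test_epoch_content_matches_trace(self, rng):
        trace = rng.normal(size=int(10 * RATE))
        eps = epoch(trace, RATE, [3.0], (0.0, 120.0))
        i0 = int(3.0 * RATE)
        assert np.array_equal(eps.epochs[0], trace[i0:i0 + eps.epochs.shape[1]])


class TestBandpass:
    def run_tone(self, freq, config):
        t = np.arange(int(0.8 * RATE)) / RATE
        x = np.sin(2 * np.pi * freq * t)
        eps = EpochSet(x[None, :], RATE, t * 1000.0 - 200.0)
        out = bandpass(eps, config)
        # compare RMS over the central half to avoid edge effects
        sl = slice(x.size // 4, 3 * x.size // 4)
        return 20 * np.log10(np.std(out.epochs[0][sl]) / np.std(x[sl]))

    def test_passband_unity(self):
        assert abs(self.run_tone(10.0, HUMAN_CONFIG)) < 1.0

    def test_line_noise_attenuated(self):
        assert self.run_tone(50.0, HUMAN_CONFIG) < -40.0

    def test_dc_removed(self):
        eps = EpochSet(np.full((1, int(0.8 * RATE)), 3.0), RATE,
                       np.arange(int(0.8 * RATE)) / RATE * 1000 - 200)
        out = bandpass(eps, HUMAN_CONFIG)
        assert np.max(np.abs(out.epochs)) < 0.2

    def test_cat_band_rejects_low_frequencies(self):
        assert self.run_tone(1.0, CAT_CONFIG) < -20.0
        assert abs(self.run_tone(10.0, CAT_CONFIG)) < 1.0


class TestRejectArtifacts:
    def test_clean_epochs_all_survive(self, rng):
        t_ms = np.arange(31) / RATE * 1000
        eps = EpochSet(rng.normal(size=(50, 31)), RATE, t_ms)
        out = reject_artifacts(eps, CAT_CONFIG)
        assert out.n_surviving == 50

    def test_cat_spike_flagged(self, rng):
        n_t = int(0.12 * RATE) + 1
        t_ms = np.arange(n_t) / RATE * 1000
        data = rng.normal(size=(40, n_t))
        data[7, 10] = 5.5 * np.median(np.sqrt(np.mean(data ** 2, axis=1)))
        eps = EpochSet(data, RATE, t_ms)
        out = reject_artifacts(eps, CAT_CONFIG)
        assert out.rejected[7]
        assert out.reject_reason[7] is not None
        assert out.n_surviving == 39

    def test_flagging_preserves_data(self, rng):
        n_t = int(0.12 * RATE) + 1
        data = rng.normal(size=(10, n_t))
        data[2] *= 20.0
        eps = EpochSet(data.copy(), RATE, np.arange(n_t) / RATE * 1000)
        out = reject_artifacts(eps, CAT_CONFIG)
        assert np.array_equal(out.epochs, data)

    def test_human_ocular_rejection_rate(self):
        # ~10 % injected ocular artifacts should be flagged at about that rate
        from dataclasses import replace

        spec = replace(HUMAN_EEG_SPEC, artifact_rate=0.1)
        conds = [{"label": "x", "probe_level_db": 70.0, "masking_db": 0.0}]
        recs, _ = gen_eeg_session(spec, conds, n_blocks=10, seed=21)
        rec = recs["x"]
        trace = derive_channel(rec, HUMAN_CONFIG)
        eps = epoch(trace, rec.rate_hz, rec.trigger_times_s, (-200.0, 600.0), True)
        eog = rec.channel("EOG_above") - rec.channel("EOG_below")
        eog_eps = epoch(eog, rec.rate_hz, rec.trigger_times_s, (-200.0, 600.0), True)
        out = reject_artifacts(eps, HUMAN_CONFIG, eog_trace=eog,
                               eog_epochs=eog_eps.epochs)
        frac = out.rejected.mean()
        assert 0.05 <= frac <= 0.15


class TestAverageAndPeaks:
    def test_identical_epochs_average_to_one(self, rng):
        x = rng.normal(size=100)
        eps = EpochSet(np.tile(x, (8, 1)), RATE, np.arange(100) / RATE * 1000)
        assert np.allclose(average_and_baseline(eps, None), x)

    def test_noise_shrinks_as_sqrt_n(self, rng):
        template = np.sin(np.linspace(0, np.pi, 200))
        resid = []
        for n in (10, 240):
            noise = rng.normal(0, 1, size=(n, 200))
            eps = EpochSet(template + noise, RATE, np.arange(200) / RATE * 1000)
            mean = average_and_baseline(eps, None)
            resid.append(np.std(mean - template))
        assert resid[1] < resid[0] / np.sqrt(240 / 10) * 1.6

    def test_baseline_offset_removed(self):
        n_t = 205
        t_ms = np.arange(n_t) / RATE * 1000 - 200.0
        eps = EpochSet(np.full((4, n_t), 3.0), RATE, t_ms)
        mean = average_and_baseline(eps, (-200.0, 0.0))
        assert np.allclose(mean, 0.0)

    def test_all_rejected_is_an_error(self, rng):
        eps = EpochSet(rng.normal(size=(3, 50)), RATE, np.arange(50) / RATE * 1000)
        eps.rejected[:] = True
        with pytest.raises(ValueError):
            average_and_baseline(eps, None)

    def test_human_template_amplitude(self):
        t_ms = np.arange(-200, 600, 1000 / RATE)
        wave = (-4.0 * np.exp(-0.5 * ((t_ms - 100) / 15) ** 2)
                + 3.0 * np.exp(-0.5 * ((t_ms - 180) / 15) ** 2))
        res = pick_peaks(wave, t_ms, HUMAN_CONFIG, RATE)
        assert res.amplitude_uv == pytest.approx(7.0, abs=0.05)
        assert res.peaks["N1"][0] == pytest.approx(100.0, abs=4.0)
        assert res.peaks["P2"][0] == pytest.approx(180.0, abs=4.0)

    def test_cat_slope_reversal_peaks(self):
        t_ms = np.arange(0, 120, 1000 / RATE)
        wave = (2.0 * np.exp(-0.5 * ((t_ms - 30) / 6) ** 2)
                - 3.0 * np.exp(-0.5 * ((t_ms - 80) / 10) ** 2))
        res = pick_peaks(wave, t_ms, CAT_CONFIG, RATE)
        assert res.amplitude_uv == pytest.approx(5.0, abs=0.1)
        assert 15 <= res.peaks["P1"][0] <= 55
        assert 55 <= res.peaks["N1"][0] <= 120

    def test_flat_waveform_has_absent_peaks(self):
        t_ms = np.arange(0, 120, 1000 / RATE)
        res = pick_peaks(np.zeros_like(t_ms), t_ms, CAT_CONFIG, RATE)
        assert np.isnan(res.peaks["P1"][0]) and np.isnan(res.peaks["N1"][0])
        assert np.isnan(res.amplitude_uv)


class TestDbReUnmasked:
    def test_equal_amplitudes(self):
        assert to_db_re_unmasked(5.0, 5.0) == 0.0

    def test_half_amplitude(self):
        assert to_db_re_unmasked(2.5, 5.0) == pytest.approx(-6.02, abs=0.005)

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            to_db_re_unmasked(-1.0, 5.0)


class TestEndToEnd:
    def test_epoch_order_invariance(self, rng):
        n_t = int(0.12 * RATE) + 1
        data = rng.normal(size=(30, n_t))
        t_ms = np.arange(n_t) / RATE * 1000
        perm = rng.permutation(30)
        a = average_and_baseline(reject_artifacts(EpochSet(data, RATE, t_ms),
                                                  CAT_CONFIG), None)
        b = average_and_baseline(reject_artifacts(EpochSet(data[perm], RATE, t_ms),
                                                  CAT_CONFIG), None)
        assert np.allclose(a, b)

    def test_recovers_injected_masking(self):
        conds = [
            {"label": "no-masker", "probe_level_db": 70.0, "masking_db": 0.0},
            {"label": "masked", "probe_level_db": 70.0, "masking_db": 40.0},
        ]
        recs, truth = gen_eeg_session(HUMAN_EEG_SPEC, conds, n_blocks=20, seed=3)
        res = {lab: run_pipeline(rec, HUMAN_CONFIG) for lab, rec in recs.items()}
        got = to_db_re_unmasked(res["masked"].amplitude_uv,
                                res["no-masker"].amplitude_uv)
        inj = 20 * np.log10(truth.true_amplitude_uv[1] / truth.true_amplitude_uv[0])
        assert got == pytest.approx(inj, abs=1.5)
        assert res["no-masker"].amplitude_uv == pytest.approx(
            truth.true_amplitude_uv[0], rel=0.10)
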