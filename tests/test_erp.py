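"""ERP chain: preprocessing, epoching, rejection, ICA, averaging, P300."""

import numpy as np
import pytest

from earpipe.erp import (EpochSet, ERPFilterConfig, ERPResult,
                         epoch_and_baseline, grand_average_and_difference,
                         ica_blink_removal, measure_p300, preprocess,
                         reject_epochs, run_erp_participant,
                         smooth_moving_average)
from earpipe.stimuli import EventSchedule, OddballSpec
from earpipe.synth import (ArtifactSpec, EEGRecording, ERPTemplate,
                           simulate_oddball_recording)


def make_schedule(onsets, labels):
    return EventSchedule(np.asarray(onsets, float), labels)


class TestPreprocess:
    def test_output_length_and_rate(self):
        rec = EEGRecording(np.random.default_rng(0).normal(size=(2, 10_000)),
                           1000.0)
        out = preprocess(rec)
        assert out.fs == 128.0
        assert out.n_samples == 1280

    def test_constant_offset_removed(self):
        rec = EEGRecording(np.full((1, 20_000), 37.0), 1000.0)
        out = preprocess(rec)
        assert np.abs(out.data).mean() < 0.01

    def test_45hz_probe_attenuated_beyond_20db(self):
        t = np.arange(60_000) / 1000
        rec = EEGRecording(np.sin(2 * np.pi * 45 * t)[None, :], 1000.0)
        out = preprocess(rec)
        core = out.data[0, 500:-500]
        assert np.abs(core).max() < 10 ** (-20 / 20)

    def test_passband_tone_preserved(self):
        t = np.arange(60_000) / 1000
        rec = EEGRecording(np.sin(2 * np.pi * 5 * t)[None, :], 1000.0)
        out = preprocess(rec)
        assert np.abs(out.data[0, 500:-500]).max() == pytest.approx(1.0, abs=0.02)

    def test_resample_above_input_rate_rejected(self):
        rec = EEGRecording(np.zeros((1, 1000)), 100.0)
        with pytest.raises(ValueError):
            preprocess(rec, ERPFilterConfig(resample_fs=128.0, lp_cutoff=30.0))


class TestEpoching:
    def test_baseline_mean_is_zero(self):
        rng = np.random.default_rng(1)
        rec = EEGRecording(rng.normal(size=(2, 128 * 20)), 128.0)
        epochs = epoch_and_baseline(rec, make_schedule([5.0, 10.0],
                                                       ["target", "standard"]))
        n_pre = np.sum(epochs.times_ms < 0)
        base = epochs.data[:, :, :n_pre].mean(axis=2)
        np.testing.assert_allclose(base, 0, atol=1e-9)

    def test_window_spans_minus500_to_1000ms(self):
        rec = EEGRecording(np.zeros((1, 128 * 10)), 128.0)
        epochs = epoch_and_baseline(rec, make_schedule([5.0], ["target"]))
        assert epochs.data.shape[-1] == 192
        assert epochs.times_ms[0] == pytest.approx(-500.0)
        assert epochs.times_ms[-1] < 1000.0

    def test_event_too_early_dropped_and_logged(self, caplog):
        rec = EEGRecording(np.zeros((1, 128 * 10)), 128.0)
        with caplog.at_level("WARNING", logger="earpipe.erp"):
            epochs = epoch_and_baseline(
                rec, make_schedule([0.1, 5.0], ["target", "standard"]))
        assert epochs.n_epochs == 1
        assert any("dropped" in m for m in caplog.messages)

    def test_default_schedule_yields_400_labelled_epochs(self):
        rec, _ = simulate_oddball_recording(seed=7, oddball=OddballSpec())
        pp = preprocess(rec)
        epochs = epoch_and_baseline(pp)
        assert epochs.n_epochs == 400
        assert epochs.labels == list(rec.schedule.labels)

    def test_all_events_outside_recording_is_error(self):
        rec = EEGRecording(np.zeros((1, 64)), 128.0)
        with pytest.raises(ValueError):
            epoch_and_baseline(rec, make_schedule([100.0], ["target"]))


class TestRejection:
    def _epochs(self, data):
        n = data.shape[0]
        times = (np.arange(data.shape[2]) - 64) / 128 * 1000
        return EpochSet(data, ["standard"] * n, times, 128.0)

    def test_identical_epochs_none_rejected(self):
        data = np.tile(np.sin(np.linspace(0, 6, 192)), (20, 2, 1))
        _, report = reject_epochs(self._epochs(data))
        assert len(report.rejected_indices) == 0

    def test_spike_epoch_caught_by_kurtosis(self):
        rng = np.random.default_rng(2)
        data = rng.normal(0, 20, (100, 3, 192))
        data[17, :, 96] += 500.0
        kept, report = reject_epochs(self._epochs(data))
        assert 17 in report.rejected_indices
        from scipy.stats import kurtosis

        assert kurtosis(data[17, 0]) > kurtosis(data[16, 0])

    def test_rejected_fraction_consistent_with_mask(self):
        rng = np.random.default_rng(3)
        data = rng.normal(0, 20, (50, 2, 192))
        kept, report = reject_epochs(self._epochs(data))
        assert report.rejected_fraction == pytest.approx(
            100 * len(report.rejected_indices) / 50)
        assert kept.keep_mask.sum() == 50 - len(report.rejected_indices)

    def test_too_few_epochs_rejected(self):
        data = np.zeros((5, 1, 192))
        with pytest.raises(ValueError):
            reject_epochs(self._epochs(data))


class TestICA:
    def test_known_mixture_recovered(self, rng):
        n, fs = 20_000, 128.0
        t = np.arange(n) / fs
        blink = np.zeros(n)
        for c in rng.uniform(5, n / fs - 5, 40):
            blink += 100 * np.exp(-0.5 * ((t - c) / 0.08) ** 2)
        sources = np.vstack([10 * np.sin(2 * np.pi * 7 * t),
                             8 * np.sign(np.sin(2 * np.pi * 3.1 * t)),
                             blink])
        mixing = np.array([[1.0, 0.5, 0.9], [0.7, 1.0, 0.4], [0.3, 0.8, 1.2]])
        rec = EEGRecording(mixing @ sources, fs)
        cleaned, record = ica_blink_removal(rec)
        corr = np.abs(np.corrcoef(np.vstack([sources,
                                             record["sources"].T]))[:3, 3:])
        assert np.all(corr.max(axis=1) > 0.95)
        # the removed component is the blink train
        assert corr[2, record["removed_index"]] > 0.95

    def test_no_blink_component_is_noop(self, rng):
        rec = EEGRecording(rng.normal(size=(3, 10_000)), 128.0)
        cleaned, record = ica_blink_removal(rec, kurtosis_floor=5.0)
        assert record["removed_index"] is None
        np.testing.assert_allclose(cleaned.data, rec.data, atol=1e-6)

    def test_blink_correlation_reduced_on_default_scenario(
            self, contaminated_recording):
        rec, log = contaminated_recording
        pp = preprocess(rec)
        cleaned, record = ica_blink_removal(pp)
        t = np.arange(pp.n_samples) / pp.fs
        reg = np.zeros(pp.n_samples)
        for e in log:
            if e["kind"] == "blink":
                reg += np.exp(-0.5 * ((t - e["time_s"]) / 0.08) ** 2)
        before = abs(np.corrcoef(pp.data[0], reg)[0, 1])
        after = abs(np.corrcoef(cleaned.data[0], reg)[0, 1])
        assert after < 0.2 * before

    def test_single_channel_rejected(self):
        rec = EEGRecording(np.zeros((1, 1000)), 128.0)
        with pytest.raises(ValueError):
            ica_blink_removal(rec)

    def test_rank_deficient_data_raises(self):
        x = np.random.default_rng(0).normal(size=10_000)
        rec = EEGRecording(np.vstack([x, x, 2 * x]), 128.0)
        with pytest.raises(np.linalg.LinAlgError):
            ica_blink_removal(rec)


class TestSmoothing:
    def test_constant_series_unchanged(self):
        out = smooth_moving_average(np.full(100, 3.5), order=8)
        np.testing.assert_allclose(out, 3.5, atol=1e-12)

    def test_white_noise_variance_reduced_ninefold(self, rng):
        x = rng.standard_normal(10_000)
        out = smooth_moving_average(x, order=8)
        assert out[50:-50].var() == pytest.approx(1 / 9, rel=0.10)

    def test_zero_phase_peak_preserved(self):
        x = np.concatenate([np.linspace(0, 1, 50), np.linspace(1, 0, 50)[1:]])
        out = smooth_moving_average(x, order=8)
        assert np.argmax(out) == np.argmax(x)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            smooth_moving_average(np.zeros(5), order=8)


class TestAveragingAndP300:
    def _epochset(self, data, labels):
        times = (np.arange(data.shape[2]) - 64) / 128 * 1000
        return EpochSet(data, labels, times, 128.0)

    def test_single_channel_participant_excluded(self):
        rng = np.random.default_rng(4)
        good = self._epochset(rng.normal(size=(10, 3, 192)),
                              ["target", "standard"] * 5)
        bad = self._epochset(rng.normal(size=(10, 1, 192)),
                             ["target", "standard"] * 5)
        result = grand_average_and_difference([good, bad, good])
        assert result.n_participants == 2

    def test_identical_conditions_give_zero_difference(self):
        x = np.random.default_rng(5).normal(size=(1, 2, 192))
        data = np.repeat(x, 10, axis=0)
        eps = self._epochset(data, ["target", "standard"] * 5)
        result = grand_average_and_difference([eps])
        np.testing.assert_allclose(result.difference, 0, atol=1e-12)

    def test_opposite_participants_cancel(self):
        rng = np.random.default_rng(6)
        base = rng.normal(size=(10, 2, 192))
        a = self._epochset(base, ["target", "standard"] * 5)
        b = self._epochset(-base, ["target", "standard"] * 5)
        result = grand_average_and_difference([a, b])
        np.testing.assert_allclose(result.target_avg, 0, atol=1e-12)

    def test_no_admissible_participant_is_error(self):
        bad = self._epochset(np.zeros((10, 1, 192)), ["target", "standard"] * 5)
        with pytest.raises(ValueError):
            grand_average_and_difference([bad])

    def test_noise_free_peak_recovery(self):
        times = (np.arange(192) - 64) / 128 * 1000
        wave = 10 * np.exp(-0.5 * ((times - 350) / 50) ** 2)
        result = ERPResult(times, wave, np.zeros_like(wave), wave, 1)
        amp, lat = measure_p300(result)
        # peak sampled on the 128 Hz grid: off-grid loss <= exp(-dt^2/2s^2)
        assert amp == pytest.approx(10.0, rel=5e-3)
        assert abs(lat - 350) <= 1000 / 128

    def test_flat_difference_ties_to_window_start(self):
        times = (np.arange(192) - 64) / 128 * 1000
        zeros = np.zeros_like(times)
        result = ERPResult(times, zeros, zeros, zeros, 1)
        amp, lat = measure_p300(result)
        assert amp == 0.0
        assert lat == times[(times >= 250)][0]

    def test_window_outside_epoch_rejected(self):
        times = (np.arange(192) - 64) / 128 * 1000
        zeros = np.zeros_like(times)
        result = ERPResult(times, zeros, zeros, zeros, 1)
        with pytest.raises(ValueError):
            measure_p300(result, search_window_ms=(2000, 3000))


class TestPipelineProperties:
    def test_linearity_up_to_rejection(self):
        rec, _ = simulate_oddball_recording(
            seed=21, oddball=OddballSpec(n_sequences=5))
        scaled = rec.copy_with(2.0 * rec.data)
        scaled.schedule = rec.schedule
        a, _ = run_erp_participant(rec, apply_ica=False, apply_rejection=False)
        b, _ = run_erp_participant(scaled, apply_ica=False,
                                   apply_rejection=False)
        ra = grand_average_and_difference([a])
        rb = grand_average_and_difference([b])
        np.testing.assert_allclose(rb.difference, 2 * ra.difference, rtol=1e-6)

    def test_parameter_recovery_single_participants(self):
        # mean over seeded single-participant runs of the full chain
        amps, lats = [], []
        for seed in (31, 32, 33, 34, 35, 36):
            rec, _ = simulate_oddball_recording(seed=seed,
                                                artifacts=ArtifactSpec())
            ep, _ = run_erp_participant(rec)
            res = grand_average_and_difference([ep])
            amp, lat = measure_p300(res)
            amps.append(amp)
            lats.append(lat)
        assert np.mean(amps) == pytest.approx(24.0, rel=0.20)
        assert abs(np.mean(lats) - 400.0) <= 40.0

    def test_rejection_improves_recovery_under_heavy_artifacts(self):
        # paired over seeds on a heavily contaminated scenario
        heavy = ArtifactSpec(blink_rate_per_min=3.0, blink_amplitude_uv=500.0,
                             muscle_burst_rate_per_min=2.0, muscle_rms_uv=80.0)
        oddball = OddballSpec(n_sequences=20)
        diffs = []
        for seed in range(1, 13):
            rec, _ = simulate_oddball_recording(seed=seed, oddball=oddball,
                                                artifacts=heavy)
            rmse = {}
            for rej in (True, False):
                ep, _ = run_erp_participant(rec, apply_ica=False,
                                            apply_rejection=rej)
                res = grand_average_and_difference([ep])
                target = 24 * np.exp(-0.5 * ((res.times_ms - 400) / 60) ** 2)
                rmse[rej] = np.sqrt(np.mean((res.difference - target) ** 2))
            diffs.append(rmse[True] - rmse[False])
        assert np.mean(diffs) < 0, diffs
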