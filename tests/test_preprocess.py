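"""Filtering, epoching, baseline, artifact screening and the online chain."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal

import affectp300 as ap
from affectp300.preprocess import design_bandpass
from affectp300.simulate import ContinuousRecording
from conftest import random_epochset

FS = 256.0


def sinusoid_recording(freq, seconds=20.0, amp=1.0):
    t = np.arange(int(FS * seconds)) / FS
    return ContinuousRecording(samples=amp * np.sin(2 * np.pi * freq * t)[None, :],
                               sample_rate=FS, channels=("Cz",))


class TestBandpass:
    def test_dc_removed(self):
        rec = ContinuousRecording(samples=np.full((1, int(FS * 30)), 5.0),
                                  sample_rate=FS, channels=("Cz",))
        out = ap.bandpass_filter(rec)
        mid = out.samples[0, int(FS * 10):int(FS * 20)]
        assert np.abs(mid).max() < 0.05

    @pytest.mark.parametrize("freq,lo,hi", [(10.0, 0.95, 1.05), (45.0, 0.0, 0.05)])
    def test_gain_matches_frequency_response_oracle(self, freq, lo, hi):
        # oracle: evaluate the designed filter's |H|^2 (zero-phase = two passes)
        sos = design_bandpass(FS)
        _, h = signal.sosfreqz(sos, worN=[freq], fs=FS)
        expected_gain = np.abs(h[0]) ** 2
        rec = sinusoid_recording(freq, seconds=40.0)
        out = ap.bandpass_filter(rec)
        # Hann-windowed projection on the tone isolates the gain at `freq`
        # from edge transients and numerical noise at other frequencies
        mid = slice(int(FS * 10), int(FS * 30))
        t = np.arange(len(rec.samples[0]))[mid] / FS
        probe = np.exp(2j * np.pi * freq * t) * np.hanning(mid.stop - mid.start)
        measured = (np.abs(out.samples[0, mid] @ probe)
                    / np.abs(rec.samples[0, mid] @ probe))
        assert measured == pytest.approx(expected_gain, rel=0.02, abs=1e-4)
        assert lo <= measured <= hi

    def test_invalid_band_edges_rejected(self):
        rec = sinusoid_recording(10.0, seconds=5.0)
        with pytest.raises(ValueError):
            ap.bandpass_filter(rec, low=20.0, high=0.1)
        with pytest.raises(ValueError):
            ap.bandpass_filter(rec, high=200.0)

    def test_linearity_of_preprocessing(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(2, int(FS * 10)))
        b = rng.normal(size=(2, int(FS * 10)))
        mk = lambda x: ContinuousRecording(samples=x, sample_rate=FS,
                                           channels=("C3", "Cz"))
        both = ap.bandpass_filter(mk(a + b)).samples
        sep = ap.bandpass_filter(mk(a)).samples + ap.bandpass_filter(mk(b)).samples
        assert np.allclose(both, sep, atol=1e-9)


class TestEpoching:
    def test_run_yields_50_epochs_with_required_windows(self, default_config):
        rec, ev = ap.generate_run(default_config, 0, 0)
        epochs = ap.extract_epochs(rec, ev)
        assert epochs.n_epochs == 50
        assert epochs.times[0] <= -100.0
        assert epochs.times[-1] >= 700.0
        assert np.allclose(np.diff(epochs.times), 1000.0 / 256)

    def test_overlapping_windows_share_signal(self, default_config):
        rec, ev = ap.generate_run(default_config, 0, 0)
        epochs = ap.extract_epochs(rec, ev)
        # events are 500 ms apart; epoch spans 900 ms -> 300+ ms overlap
        t = epochs.times
        k = np.nonzero(t >= 400)[0][0]
        overlap_a = epochs.data[0, :, k:]
        n_shared = overlap_a.shape[1]
        shift = np.nonzero(t >= t[k] - 500)[0][0]
        overlap_b = epochs.data[1, :, shift:shift + n_shared]
        assert np.allclose(overlap_a, overlap_b)

    def test_edge_event_flagged_rejected(self, default_config):
        rec, ev = ap.generate_run(default_config, 0, 0)
        bad = ap.EventList(onsets=np.array([5, ev.onsets[1]]),
                           stimulus_ids=ev.stimulus_ids[:2],
                           run_id=1, session_id=1, part_id=1, target_id=1)
        epochs = ap.extract_epochs(rec, bad)
        assert bool(epochs.info.rejected[0]) is True
        assert bool(epochs.info.rejected[1]) is False

    def test_sequence_index_counts_occurrences(self, default_config):
        rec, ev = ap.generate_run(default_config, 0, 0)
        epochs = ap.extract_epochs(rec, ev)
        for sid in range(1, 6):
            seq = epochs.info.loc[epochs.info.stimulus_id == sid,
                                  "sequence_index"]
            assert sorted(seq) == list(range(1, 11))


class TestBaseline:
    def test_zero_mean_and_idempotent(self):
        rng = np.random.default_rng(1)
        epochs = random_epochset(rng, n_times=300)
        epochs.times = epochs.times - 120.0  # ensure a [-100, 0] interval
        out = ap.baseline_correct(epochs)
        mask = (out.times >= -100) & (out.times <= 0)
        assert np.abs(out.data[:, :, mask].mean(axis=2)).max() < 1e-9
        again = ap.baseline_correct(out)
        assert np.allclose(again.data, out.data)

    def test_constant_offset_removed(self):
        rng = np.random.default_rng(2)
        epochs = random_epochset(rng, n_times=300)
        epochs.times = epochs.times - 120.0
        epochs.data[:] = 7.5
        out = ap.baseline_correct(epochs)
        assert np.allclose(out.data, 0.0)

    def test_empty_interval_rejected(self):
        rng = np.random.default_rng(3)
        epochs = random_epochset(rng)
        with pytest.raises(ValueError):
            ap.baseline_correct(epochs, interval=(-500.0, -400.0))


class TestArtifactScreen:
    def make(self, peak):
        rng = np.random.default_rng(4)
        epochs = random_epochset(rng, n_epochs=3)
        epochs.data[:] = 0.0
        epochs.data[1, 0, 5] = peak
        return epochs

    def test_rejection_is_strict_at_threshold(self):
        assert not ap.reject_artifacts(self.make(80.0)).info.rejected.any()
        out = ap.reject_artifacts(self.make(80.0001))
        assert out.info.rejected.tolist() == [False, True, False]
        assert not ap.reject_artifacts(self.make(0.0)).info.rejected.any()

    def test_zeroing_replaces_samples_and_flags(self):
        out = ap.zero_outlier_epochs(self.make(100.0))
        assert out.info.zeroed.tolist() == [False, True, False]
        assert np.allclose(out.data[1], 0.0)
        assert not out.info.zeroed[0]
        # labels untouched
        assert (out.info.stimulus_id == self.make(100.0).info.stimulus_id).all()

    def test_labels_never_mutated_by_chain(self, default_config):
        rec, ev = ap.generate_run(default_config, 0, 3)
        raw = ap.extract_epochs(rec, ev).info[["stimulus_id", "run_id",
                                               "sequence_index"]]
        processed = ap.preprocess_run(rec, ev)
        assert processed.info[["stimulus_id", "run_id",
                               "sequence_index"]].equals(raw)


class TestAverages:
    def test_condition_counts(self, subject_epochs):
        averages = ap.grand_average(subject_epochs)
        assert len(averages) == 10  # 5 sounds x target/non-target
        for avg in averages:
            limit = 100 if avg.is_target else 400
            assert 0 < avg.n_epochs <= limit

    def test_averaging_identical_epochs_is_identity(self):
        rng = np.random.default_rng(5)
        epochs = random_epochset(rng, n_epochs=4)
        epochs.data[:] = epochs.data[0]
        epochs.info["stimulus_id"] = 1
        epochs.info["is_target"] = True
        avg = ap.grand_average(epochs)
        assert np.allclose(avg[0].data, epochs.data[0])

    def test_noise_free_target_average_recovers_template(self):
        """With isolated events (wide SOA) and no noise, the target-epoch
        average reproduces the generator template to numerical precision."""
        from affectp300.simulate import _template_matrix

        cfg = ap.SimConfig(noise_sd=0.0, subject_amp_range=(1.0, 1.0),
                           subject_latency_jitter_ms=0.0, soa=2000.0, seed=3)
        rec, ev = ap.generate_run(cfg, 0, 0)
        epochs = ap.extract_epochs(rec, ev)
        tgt = epochs.select(epochs.info.is_target.to_numpy())
        avg = tgt.data.mean(axis=0)
        tmpl = _template_matrix(cfg, True, cfg.true_valences[ev.target_id - 1],
                                1.0, 0.0)
        pos = np.nonzero(epochs.times >= 0)[0]
        n = min(len(pos), tmpl.shape[1])
        assert np.allclose(avg[:, pos[:n]], tmpl[:, :n], atol=1e-12)

    def test_fully_rejected_condition_is_an_error(self):
        rng = np.random.default_rng(6)
        epochs = random_epochset(rng, n_epochs=4)
        epochs.info["stimulus_id"] = 1
        epochs.info["is_target"] = False
        epochs.info["rejected"] = True
        with pytest.raises(ValueError, match="stimulus 1"):
            ap.grand_average(epochs)


class TestOnlineChain:
    def test_constant_preserved_and_rate_reduced(self):
        rng = np.random.default_rng(7)
        epochs = random_epochset(rng, n_times=230)
        epochs.data[:] = 3.25
        out = ap.online_feature_chain(epochs)
        assert np.allclose(out.data, 3.25)
        assert np.isclose(np.diff(out.times)[0], 4 * np.diff(epochs.times)[0])
        assert out.sample_rate == pytest.approx(64.0)

    def test_quintic_reproduced_by_savgol_stage(self):
        rng = np.random.default_rng(8)
        epochs = random_epochset(rng, n_times=230)
        x = np.linspace(-1, 1, 230)
        poly = 2 * x**5 - x**3 + 0.5 * x**2 - x + 0.1
        epochs.data[:] = poly
        out = ap.online_feature_chain(epochs, smooth_window=1)
        dec = poly[::4]
        interior = slice(25, len(dec) - 25)  # away from edge handling
        assert np.allclose(out.data[0, 0, interior], dec[interior], atol=1e-8)

    def test_short_epoch_rejected(self):
        rng = np.random.default_rng(9)
        epochs = random_epochset(rng, n_times=60)
        with pytest.raises(ValueError):
            ap.online_feature_chain(epochs)


def test_filter_order_epochs_vs_continuous_agree_on_clean_data():
    """Filtering the continuous signal then epoching ~= filtering a widely
    padded epoch: the two orders differ only by edge transients, which decay
    well before the epoch window when the padding is generous."""
    cfg = ap.SimConfig(noise_sd=0.0, subject_amp_range=(1.0, 1.0),
                       subject_latency_jitter_ms=0.0, seed=4)
    rec, ev = ap.generate_run(cfg, 0, 0)
    fs = int(cfg.sample_rate)
    order_a = ap.extract_epochs(ap.bandpass_filter(rec), ev)
    onset = int(ev.onsets[20])  # mid-run event, 8 s of context either side
    wide = rec.samples[:, onset - 8 * fs:onset + 8 * fs]
    sos = design_bandpass(cfg.sample_rate)
    wide_f = signal.sosfiltfilt(sos, wide, axis=1)
    crop = wide_f[:, 8 * fs - 26:8 * fs - 26 + 230]
    scale = np.abs(order_a.data[20]).max()
    assert np.allclose(order_a.data[20], crop, atol=2e-2 * scale)
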