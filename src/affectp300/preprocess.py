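"""ERP preprocessing: band-pass filtering, epoching, baseline, artifact screening.

The chain mirrors standard oddball-ERP practice: a 6th-order Butterworth
band-pass (0.1-20 Hz, zero-phase by default) applied to the continuous
recording, epoching into [-100, 800) ms windows around each stimulus onset,
baseline removal from the -100..0 ms mean, and an 80 uV peak-amplitude screen.
The screen has two modes matching how training and test data are treated:
offending training epochs are *rejected* (dropped from averages and classifier
fits) while offending test epochs are *zeroed* (all samples set to 0) so they
contribute nothing to the score sums.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from scipy.ndimage import uniform_filter1d

from .simulate import ContinuousRecording, EventList

logger = logging.getLogger(__name__)

LABEL_COLUMNS = ["stimulus_id", "is_target", "run_id", "session_id",
                 "part_id", "sequence_index", "rejected", "zeroed"]


@dataclass
class EpochSet:
    """Stack of ERP epochs with per-epoch labels.

    ``data`` is (n_epochs, n_channels, n_times) in microvolts; ``times`` is the
    epoch time axis in milliseconds relative to stimulus onset; ``info`` is a
    DataFrame with one row per epoch (columns ``LABEL_COLUMNS``).
    ``sequence_index`` counts the s-th occurrence (1-based) of an epoch's
    stimulus within its run.
    """

    data: np.ndarray
    times: np.ndarray
    channels: tuple[str, ...]
    info: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("data must be (n_epochs, n_channels, n_times)")
        if self.data.shape[0] != len(self.info):
            raise ValueError("info must have one row per epoch")
        if self.data.shape[1] != len(self.channels):
            raise ValueError("channel labels do not match data")
        if self.data.shape[2] != len(self.times):
            raise ValueError("time axis does not match data")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def sample_rate(self) -> float:
        return 1000.0 / float(np.median(np.diff(self.times)))

    def copy(self) -> "EpochSet":
        return EpochSet(self.data.copy(), self.times.copy(), self.channels,
                        self.info.copy())

    def select(self, mask) -> "EpochSet":
        """Subset by boolean mask or integer index over epochs."""
        mask = np.asarray(mask)
        return EpochSet(self.data[mask], self.times, self.channels,
                        self.info.iloc[mask].reset_index(drop=True))

    def retained(self) -> "EpochSet":
        """Epochs not flagged as artifact-rejected."""
        return self.select(~self.info["rejected"].to_numpy())


@dataclass(frozen=True)
class AverageERP:
    """Condition-average waveform (channel x time) with the epoch count used."""

    stimulus_id: int
    is_target: bool
    data: np.ndarray  # (n_channels, n_times)
    times: np.ndarray
    channels: tuple[str, ...]
    n_epochs: int


def design_bandpass(sample_rate: float, low: float = 0.1, high: float = 20.0,
                    order: int = 6):
    """Second-order sections of the Butterworth band-pass used throughout."""
    if not (0 < low < high < sample_rate / 2):
        raise ValueError("need 0 < low < high < Nyquist")
    return signal.butter(order, [low, high], btype="bandpass", fs=sample_rate,
                         output="sos")


def bandpass_filter(recording: ContinuousRecording, low: float = 0.1,
                    high: float = 20.0, order: int = 6,
                    zero_phase: bool = True) -> ContinuousRecording:
    """Butterworth band-pass per channel.

    Zero-phase (forward-backward) application is the default so component
    latencies are preserved; note this doubles the effective filter order.
    Set ``zero_phase=False`` for a causal single pass.
    """
    sos = design_bandpass(recording.sample_rate, low, high, order)
    if zero_phase:
        filtered = signal.sosfiltfilt(sos, recording.samples, axis=1)
    else:
        filtered = signal.sosfilt(sos, recording.samples, axis=1)
    return ContinuousRecording(samples=np.ascontiguousarray(filtered),
                               sample_rate=recording.sample_rate,
                               channels=recording.channels)


def _window_samples(sample_rate: float, start_ms: float, stop_ms: float
                    ) -> tuple[int, int]:
    """Sample offset of the first sample and sample count for [start, stop) ms."""
    k0 = int(math.floor(start_ms * sample_rate / 1000.0 + 1e-9))
    n = int(math.floor((stop_ms - start_ms) * sample_rate / 1000.0 + 1e-9))
    return k0, n


def extract_epochs(recording: ContinuousRecording, events: EventList,
                   window: tuple[float, float] = (-100.0, 800.0)) -> EpochSet:
    """Cut one epoch per event from the continuous recording.

    Windows may overlap (the 500 ms SOA is shorter than the epoch); each epoch
    is extracted independently.  Events too close to a recording edge yield a
    zero-filled epoch flagged ``rejected``.
    """
    fs = recording.sample_rate
    k0, n_samp = _window_samples(fs, *window)
    times = (k0 + np.arange(n_samp)) / fs * 1000.0
    n_ev = len(events.onsets)
    data = np.zeros((n_ev, len(recording.channels), n_samp))
    rejected = np.zeros(n_ev, dtype=bool)
    n_total = recording.samples.shape[1]
    seq_count: dict[int, int] = {}
    seq_index = np.zeros(n_ev, dtype=int)
    for e, (onset, sid) in enumerate(zip(events.onsets, events.stimulus_ids)):
        seq_count[sid] = seq_count.get(sid, 0) + 1
        seq_index[e] = seq_count[sid]
        start = int(onset) + k0
        stop = start + n_samp
        if start < 0 or stop > n_total:
            rejected[e] = True
            logger.warning("event at sample %d of run %d too close to edge; "
                           "epoch rejected", onset, events.run_id)
            continue
        data[e] = recording.samples[:, start:stop]
    info = pd.DataFrame({
        "stimulus_id": np.asarray(events.stimulus_ids, dtype=int),
        "is_target": np.asarray(events.stimulus_ids) == events.target_id,
        "run_id": events.run_id,
        "session_id": events.session_id,
        "part_id": events.part_id,
        "sequence_index": seq_index,
        "rejected": rejected,
        "zeroed": False,
    })
    return EpochSet(data=data, times=times, channels=tuple(recording.channels),
                    info=info)


def baseline_correct(epochs: EpochSet,
                     interval: tuple[float, float] = (-100.0, 0.0)) -> EpochSet:
    """Subtract the per-epoch, per-channel mean over ``interval`` (closed, ms)."""
    lo, hi = interval
    mask = (epochs.times >= lo - 1e-9) & (epochs.times <= hi + 1e-9)
    if not mask.any():
        raise ValueError(f"baseline interval {interval} contains no samples")
    out = epochs.copy()
    out.data -= out.data[:, :, mask].mean(axis=2, keepdims=True)
    return out


def _peak_amplitude(data: np.ndarray) -> np.ndarray:
    """Max |amplitude| per epoch over all channels and samples."""
    return np.abs(data).max(axis=(1, 2))


def reject_artifacts(epochs: EpochSet, threshold: float = 80.0) -> EpochSet:
    """Flag epochs whose peak |amplitude| strictly exceeds ``threshold`` uV.

    Rejected epochs are kept in place (labels intact) but are excluded from
    averages and classifier training.  The criterion is strict: an epoch
    peaking at exactly the threshold is retained.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    out = epochs.copy()
    bad = _peak_amplitude(out.data) > threshold
    out.info["rejected"] = out.info["rejected"].to_numpy() | bad
    return out


def zero_outlier_epochs(epochs: EpochSet, threshold: float = 80.0) -> EpochSet:
    """Test-time counterpart of rejection: zero out over-threshold epochs.

    Offending epochs have every sample replaced by 0 and are flagged
    ``zeroed``; labels are preserved.  A zeroed epoch's classifier score is
    the intercept-only contribution, identical across stimuli.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    out = epochs.copy()
    bad = _peak_amplitude(out.data) > threshold
    out.data[bad] = 0.0
    out.info["zeroed"] = out.info["zeroed"].to_numpy() | bad
    return out


def grand_average(epochs: EpochSet) -> list[AverageERP]:
    """Mean waveform per (stimulus, target/non-target) condition.

    Rejected epochs are excluded.  With five sounds this yields 10 conditions;
    an empty condition raises, naming it.
    """
    keep = epochs.retained()
    out: list[AverageERP] = []
    conditions = sorted(
        {(int(s), bool(t)) for s, t in
         zip(epochs.info["stimulus_id"], epochs.info["is_target"])})
    for sid, is_t in conditions:
        mask = ((keep.info["stimulus_id"] == sid)
                & (keep.info["is_target"] == is_t)).to_numpy()
        if not mask.any():
            raise ValueError(
                f"no retained epochs for stimulus {sid}, "
                f"{'target' if is_t else 'non-target'}")
        out.append(AverageERP(stimulus_id=sid, is_target=is_t,
                              data=keep.data[mask].mean(axis=0),
                              times=keep.times, channels=keep.channels,
                              n_epochs=int(mask.sum())))
    return out


def online_feature_chain(epochs: EpochSet, smooth_window: int = 4,
                         savgol_order: int = 5, savgol_window: int = 81,
                         decimate_to: float = 64.0) -> EpochSet:
    """Feature chain of the online system, for parity checks only.

    Moving-average smoothing (4-sample window), Savitzky-Golay filtering
    (order 5, 81-sample window), then decimation from 256 Hz to 64 Hz.  The
    offline headline analysis does not use it (those features keep the full
    sampling rate).
    """
    if epochs.data.shape[2] < savgol_window:
        raise ValueError("epoch shorter than the Savitzky-Golay window")
    fs = epochs.sample_rate
    factor = int(round(fs / decimate_to))
    smoothed = uniform_filter1d(epochs.data, size=smooth_window, axis=2,
                                mode="nearest")
    smoothed = signal.savgol_filter(smoothed, savgol_window, savgol_order,
                                    axis=2, mode="interp")
    out = EpochSet(data=np.ascontiguousarray(smoothed[:, :, ::factor]),
                   times=epochs.times[::factor].copy(),
                   channels=epochs.channels,
                   info=epochs.info.copy())
    return out


def preprocess_run(recording: ContinuousRecording, events: EventList,
                   low: float = 0.1, high: float = 20.0, order: int = 6,
                   window: tuple[float, float] = (-100.0, 800.0),
                   baseline: tuple[float, float] = (-100.0, 0.0),
                   reject_threshold: float = 80.0,
                   zero_phase: bool = True) -> EpochSet:
    """Full chain for one run: filter -> epoch -> baseline -> artifact screen."""
    filtered = bandpass_filter(recording, low, high, order, zero_phase)
    epochs = extract_epochs(filtered, events, window)
    epochs = baseline_correct(epochs, baseline)
    return reject_artifacts(epochs, reject_threshold)


def concat_epochs(parts: list[EpochSet]) -> EpochSet:
    """Stack EpochSets that share channel and time axes."""
    first = parts[0]
    for p in parts[1:]:
        if p.channels != first.channels or not np.allclose(p.times, first.times):
            raise ValueError("epoch sets are not axis-compatible")
    return EpochSet(
        data=np.concatenate([p.data for p in parts], axis=0),
        times=first.times.copy(), channels=first.channels,
        info=pd.concat([p.info for p in parts], ignore_index=True))


def preprocess_subject(runs: list[tuple[ContinuousRecording, EventList]],
                       **kwargs) -> EpochSet:
    """Preprocess and concatenate all runs of one subject."""
    return concat_epochs([preprocess_run(rec, ev, **kwargs)
                          for rec, ev in runs])
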