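"""Synthetic oddball EEG with valence-modulated late P300, plus simulated ratings.

The generator reproduces the structure of a five-class auditory oddball
experiment: per subject, 2 parts x 5 sessions x 5 runs = 50 runs; per run the
five sounds are played 10 times each at a 500 ms stimulus onset asynchrony
while the subject silently counts one designated target sound.  Target events
carry a late P300-like positivity over the central channels whose amplitude
follows a thresholded-linear law in |valence|, so only strongly positive or
strongly negative sounds boost the component — the ground truth the analysis
modules are meant to recover.

Units are microvolts and milliseconds throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

#: 10-20 montage used by the recordings, mastoid referenced.
DEFAULT_CHANNELS: tuple[str, ...] = ("C3", "Cz", "C4", "P3", "Pz", "P4", "O1", "O2")

# Scalp weighting of the simulated components.  Early auditory components are
# fronto-central and broad; the late P300-like positivity is strongest over
# C3/Cz/C4 (motor/vertex) with parietal spill-over and little occipital share.
_EARLY_WEIGHTS = {
    "C3": 0.85, "Cz": 1.0, "C4": 0.85,
    "P3": 0.55, "Pz": 0.65, "P4": 0.55,
    "O1": 0.35, "O2": 0.35,
}
_LATE_WEIGHTS = {
    "C3": 0.85, "Cz": 1.0, "C4": 0.85,
    "P3": 0.50, "Pz": 0.60, "P4": 0.50,
    "O1": 0.20, "O2": 0.20,
}

# Component timing (ms) and widths (Gaussian sd, ms).
_N1_LATENCY, _N1_SD, _N1_AMP = 100.0, 20.0, -4.0
_P2_LATENCY, _P2_SD, _P2_AMP = 200.0, 25.0, 3.0
_P300_LATENCY, _P300_SD = 520.0, 70.0


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the simulated experiment.

    Defaults reproduce the study design: 18 subjects, 50 runs each, five
    sounds with true valences (-2, -1, 0, 1, 2), 8 channels at 256 Hz.
    ``p300_base_amp`` is the late-component amplitude for any target;
    ``p300_valence_gain`` adds ``gain * max(0, |v| - valence_threshold)``
    microvolts on top, so with the default threshold of 1 only the +/-2
    sounds are enhanced.
    """

    n_subjects: int = 18
    n_parts: int = 2
    sessions_per_part: int = 5
    runs_per_session: int = 5
    n_stimuli: int = 5
    reps_per_stimulus: int = 10
    soa: float = 500.0  # ms
    sample_rate: float = 256.0  # Hz
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    true_valences: tuple[float, ...] = (-2.0, -1.0, 0.0, 1.0, 2.0)
    p300_base_amp: float = 1.8  # uV
    p300_valence_gain: float = 1.8  # uV per unit excess |valence|
    valence_threshold: float = 1.0
    noise_sd: float = 9.0  # uV, broadband, per channel
    pink_fraction: float = 0.5  # share of noise variance with 1/f spectrum
    subject_amp_range: tuple[float, float] = (0.8, 1.2)
    subject_latency_jitter_ms: float = 30.0
    rating_noise_sd: float = 0.6
    rating_order_effect: float = 0.1
    artifact_rate: float = 0.0  # per-event probability of a large spike
    artifact_amp: float = 150.0  # uV
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stimuli < 2 or self.reps_per_stimulus < 1:
            raise ValueError("need at least 2 stimuli and 1 repetition")
        if len(self.true_valences) != self.n_stimuli:
            raise ValueError("true_valences must have one entry per stimulus")
        if self.sample_rate <= 0 or self.soa <= 0:
            raise ValueError("sample_rate and soa must be positive")

    @property
    def runs_per_subject(self) -> int:
        return self.n_parts * self.sessions_per_part * self.runs_per_session

    @property
    def events_per_run(self) -> int:
        return self.n_stimuli * self.reps_per_stimulus

    @property
    def soa_samples(self) -> int:
        step = self.soa * self.sample_rate / 1000.0
        if abs(step - round(step)) > 1e-9:
            raise ValueError("soa must be an integer number of samples")
        return int(round(step))


@dataclass(frozen=True)
class EventList:
    """Stimulus onsets (sample indices) and labels for one run."""

    onsets: np.ndarray  # int, sample index of each stimulus onset
    stimulus_ids: np.ndarray  # int in 1..n_stimuli
    run_id: int
    session_id: int
    part_id: int
    target_id: int

    def __post_init__(self) -> None:
        if len(self.onsets) != len(self.stimulus_ids):
            raise ValueError("onsets and stimulus_ids must align")


@dataclass(frozen=True)
class ContinuousRecording:
    """Multi-channel continuous EEG in microvolts."""

    samples: np.ndarray  # (n_channels, n_times)
    sample_rate: float
    channels: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.samples.ndim != 2 or self.samples.shape[0] != len(self.channels):
            raise ValueError("samples must be (n_channels, n_times)")


def build_run_sequence(n_stimuli: int, reps: int, seed) -> np.ndarray:
    """Pseudo-random stimulus order for one run.

    The order is blockwise: each consecutive block of ``n_stimuli`` events is
    a shuffled permutation of all stimulus ids, so every stimulus occurs
    exactly once per sequence (repetition block).  This makes the per-sequence
    indexing of the score-sum classifier well defined.
    """
    if n_stimuli < 2 or reps < 1:
        raise ValueError("need n_stimuli >= 2 and reps >= 1")
    rng = np.random.default_rng(seed)
    ids = np.arange(1, n_stimuli + 1)
    return np.concatenate([rng.permutation(ids) for _ in range(reps)])


def late_p300_amplitude(valence: float, base_amp: float, gain: float,
                        threshold: float) -> float:
    """Thresholded-linear valence -> amplitude law for the late component."""
    return base_amp + gain * max(0.0, abs(valence) - threshold)


def erp_template(is_target: bool, valence: float, channel: str,
                 t: np.ndarray, *, p300_base_amp: float = 1.8,
                 p300_valence_gain: float = 1.8, valence_threshold: float = 1.0,
                 amp_scale: float = 1.0, latency_shift_ms: float = 0.0) -> np.ndarray:
    """Evoked-response template on the millisecond grid ``t``.

    Non-targets carry the early exogenous pair only (negativity near 100 ms,
    positivity near 200 ms).  Targets add a late Gaussian positivity peaking
    around 520 ms whose scalp weighting is maximal at C3/Cz/C4 and whose
    amplitude is ``base + gain * max(0, |valence| - threshold)``.
    """
    t = np.asarray(t, dtype=float)
    if t.min() > 0 or t.max() < 800:
        raise ValueError("template grid must cover 0-800 ms")
    we = _EARLY_WEIGHTS.get(channel, 0.5)
    wave = we * (_N1_AMP * np.exp(-0.5 * ((t - _N1_LATENCY) / _N1_SD) ** 2)
                 + _P2_AMP * np.exp(-0.5 * ((t - _P2_LATENCY) / _P2_SD) ** 2))
    if is_target:
        wl = _LATE_WEIGHTS.get(channel, 0.4)
        amp = late_p300_amplitude(valence, p300_base_amp, p300_valence_gain,
                                  valence_threshold)
        peak = _P300_LATENCY + latency_shift_ms
        wave = wave + wl * amp * np.exp(-0.5 * ((t - peak) / _P300_SD) ** 2)
    return amp_scale * wave


def _template_matrix(config: SimConfig, is_target: bool, valence: float,
                     amp_scale: float, latency_shift: float) -> np.ndarray:
    """(n_channels, n_samples) template evaluated on the sample grid."""
    n = int(math.ceil(0.85 * config.sample_rate)) + 1  # covers 0..~850 ms
    t = np.arange(n) / config.sample_rate * 1000.0
    return np.stack([
        erp_template(is_target, valence, ch, t,
                     p300_base_amp=config.p300_base_amp,
                     p300_valence_gain=config.p300_valence_gain,
                     valence_threshold=config.valence_threshold,
                     amp_scale=amp_scale, latency_shift_ms=latency_shift)
        for ch in config.channels
    ])


def _pink_noise(rng: np.random.Generator, n_channels: int, n_times: int,
                sample_rate: float) -> np.ndarray:
    """Unit-variance noise with 1/f power spectrum, independent per channel."""
    n_freq = n_times // 2 + 1
    spec = rng.standard_normal((n_channels, n_freq)) \
        + 1j * rng.standard_normal((n_channels, n_freq))
    freqs = np.fft.rfftfreq(n_times, d=1.0 / sample_rate)
    freqs[0] = freqs[1]  # avoid the DC singularity
    spec /= np.sqrt(freqs)  # power ~ 1/f
    x = np.fft.irfft(spec, n=n_times, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _noise(rng: np.random.Generator, config: SimConfig,
           n_times: int) -> np.ndarray:
    nch = len(config.channels)
    white = rng.standard_normal((nch, n_times))
    if config.pink_fraction <= 0:
        mix = white
    else:
        pink = _pink_noise(rng, nch, n_times, config.sample_rate)
        mix = (math.sqrt(1.0 - config.pink_fraction) * white
               + math.sqrt(config.pink_fraction) * pink)
    return config.noise_sd * mix


def subject_profile(config: SimConfig, subject: int) -> tuple[float, float]:
    """Per-subject (amplitude factor, latency shift in ms), reproducible."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7, subject]))
    lo, hi = config.subject_amp_range
    amp = float(rng.uniform(lo, hi))
    j = config.subject_latency_jitter_ms
    lat = float(rng.uniform(-j, j)) if j > 0 else 0.0
    return amp, lat


def _session_targets(config: SimConfig, subject: int, part: int,
                     session: int) -> np.ndarray:
    """Order in which the stimuli serve as targets within one session."""
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 11, subject, part, session]))
    return rng.permutation(np.arange(1, config.n_stimuli + 1))


def generate_run(config: SimConfig, subject: int, run_index: int
                 ) -> tuple[ContinuousRecording, EventList]:
    """Simulate one run (recording + events), reproducible from (seed, subject, run)."""
    rps = config.runs_per_session
    spp = config.sessions_per_part
    part = run_index // (spp * rps) + 1
    session = (run_index % (spp * rps)) // rps + 1
    run_in_session = run_index % rps
    target = int(_session_targets(config, subject, part, session)[run_in_session])

    seq = build_run_sequence(
        config.n_stimuli, config.reps_per_stimulus,
        np.random.SeedSequence([config.seed, 13, subject, run_index]))

    pad = int(round(config.sample_rate))  # 1 s before first / after last onset
    step = config.soa_samples
    onsets = pad + step * np.arange(config.events_per_run)
    n_times = int(onsets[-1] + 1 + pad)

    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 17, subject, run_index]))
    if config.noise_sd > 0:
        data = _noise(rng, config, n_times)
    else:
        data = np.zeros((len(config.channels), n_times))

    amp_scale, lat_shift = subject_profile(config, subject)
    tgt_tmpl = _template_matrix(config, True,
                                config.true_valences[target - 1],
                                amp_scale, lat_shift)
    nt_tmpl = _template_matrix(config, False, 0.0, amp_scale, lat_shift)
    tlen = tgt_tmpl.shape[1]
    for onset, sid in zip(onsets, seq):
        tmpl = tgt_tmpl if sid == target else nt_tmpl
        stop = min(onset + tlen, n_times)
        data[:, onset:stop] += tmpl[:, : stop - onset]

    if config.artifact_rate > 0:
        for onset in onsets:
            if rng.uniform() < config.artifact_rate:
                k = int(onset + rng.integers(0, step))
                data[:, k] += config.artifact_amp * rng.choice([-1.0, 1.0])

    recording = ContinuousRecording(samples=data,
                                    sample_rate=config.sample_rate,
                                    channels=config.channels)
    events = EventList(onsets=onsets.astype(int),
                       stimulus_ids=np.asarray(seq, dtype=int),
                       run_id=run_index + 1, session_id=session,
                       part_id=part, target_id=target)
    return recording, events


def generate_subject_recording(config: SimConfig, subject: int
                               ) -> list[tuple[ContinuousRecording, EventList]]:
    """All runs of one subject (50 under defaults)."""
    return [generate_run(config, subject, r)
            for r in range(config.runs_per_subject)]


def simulate_ratings(true_valences, n_subjects: int, noise_sd: float = 0.6,
                     order_effect: float = 0.1, seed=0) -> pd.DataFrame:
    """Simulated paired-comparison valence ratings.

    For every subject and every ordered pair (first=i, second=j, i != j) the
    rating is ``round(clip(v_j - v_i + order_effect + noise, -3, 3))`` — a
    positive rating means the second sound sounded more positive.  Columns:
    subject, first_id, second_id, rating.
    """
    v = np.asarray(true_valences, dtype=float)
    t = len(v)
    if t < 2:
        raise ValueError("need at least 2 stimuli")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 23]))
    rows = []
    for k in range(1, n_subjects + 1):
        for i in range(1, t + 1):
            for j in range(1, t + 1):
                if i == j:
                    continue
                y = v[j - 1] - v[i - 1] + order_effect
                if noise_sd > 0:
                    y += rng.normal(0.0, noise_sd)
                rows.append((k, i, j, int(np.clip(np.rint(y), -3, 3))))
    return pd.DataFrame(rows, columns=["subject", "first_id", "second_id",
                                       "rating"])


def null_config(config: SimConfig | None = None) -> SimConfig:
    """Copy of a config with the late component switched off (chance-level data)."""
    cfg = config or SimConfig()
    return replace(cfg, p300_base_amp=0.0, p300_valence_gain=0.0)
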