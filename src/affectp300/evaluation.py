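"""Stimulus-wise classification accuracy and its statistical comparison.

Features are raw-rate ERP samples from a spatio-temporal region of interest
(default C3/Cz/C4, 400-700 ms).  A run is classified by summing each
stimulus' SWLDA scores over its first S sequences and taking the argmax:

    i_hat = argmax_i  sum_{s=1..S}  w . x_{s,i}

The stimulus-wise leave-one-run-out cross-validation trains on the 9 other
runs in which a sound was the counted target and tests on the held-out run;
accuracy per sound and S is #correct runs / 10.  Curves over S are compared
with a two-way repeated-measures ANOVA (stimulus x number of sequences) and
post-hoc paired t-tests.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.anova import AnovaRM
from statsmodels.stats.multitest import multipletests

from .preprocess import EpochSet, _window_samples, zero_outlier_epochs
from .swlda import SWLDAConfig, SWLDAModel, swlda_fit, swlda_score

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ROISpec:
    """Channel subset and half-open time window (ms) the features come from."""

    channels: tuple[str, ...] = ("C3", "Cz", "C4")
    window: tuple[float, float] = (400.0, 700.0)


@dataclass(frozen=True)
class AccuracyTable:
    """Long-form accuracies: one row per (subject, stimulus, S)."""

    frame: pd.DataFrame  # columns: subject, stimulus, S, accuracy
    n_runs: int = 10

    def summary(self) -> pd.DataFrame:
        """Mean and standard error per stimulus x S."""
        g = self.frame.groupby(["stimulus", "S"])["accuracy"]
        out = g.agg(["mean", "sem", "count"]).reset_index()
        return out.rename(columns={"sem": "se", "count": "n_subjects"})

    def at_sequences(self, S: int) -> pd.DataFrame:
        """Wide subject x stimulus accuracy matrix at a fixed S."""
        sub = self.frame[self.frame["S"] == S]
        return sub.pivot(index="subject", columns="stimulus",
                         values="accuracy")


def roi_extract(epochs: EpochSet, roi: ROISpec | None = None) -> np.ndarray:
    """Flatten each epoch's ROI samples into a feature vector.

    Order is channel-major, time-minor and reproducible.  The number of time
    samples kept is ``floor(window_length * fs / 1000)`` starting at the first
    sample at or after the window onset — 76 per channel (228 features for 3
    channels) for 400-700 ms at 256 Hz.  No downsampling is applied.
    """
    roi = roi or ROISpec()
    missing = [c for c in roi.channels if c not in epochs.channels]
    if missing:
        raise ValueError(f"ROI channels not in montage: {missing}")
    ch_idx = [epochs.channels.index(c) for c in roi.channels]
    fs = epochs.sample_rate
    _, n_samp = _window_samples(fs, *roi.window)
    start_candidates = np.nonzero(epochs.times >= roi.window[0] - 1e-9)[0]
    if len(start_candidates) == 0 or start_candidates[0] + n_samp > len(epochs.times):
        raise ValueError(f"ROI window {roi.window} not covered by epoch")
    start = int(start_candidates[0])
    block = epochs.data[:, ch_idx, start:start + n_samp]
    return block.reshape(epochs.n_epochs, -1)


def sequence_scores(model: SWLDAModel, run_epochs: EpochSet,
                    roi: ROISpec | None = None,
                    stimuli: list[int] | None = None) -> np.ndarray:
    """(n_sequences x n_stimuli) score matrix for one run."""
    roi = roi or ROISpec()
    feats = roi_extract(run_epochs, roi)
    scores = swlda_score(model, feats)
    stimuli = stimuli or sorted(run_epochs.info["stimulus_id"].unique())
    seq = run_epochs.info["sequence_index"].to_numpy()
    sid = run_epochs.info["stimulus_id"].to_numpy()
    n_seq = int(seq.max())
    out = np.zeros((n_seq, len(stimuli)))
    for col, i in enumerate(stimuli):
        for s in range(1, n_seq + 1):
            mask = (sid == i) & (seq == s)
            out[s - 1, col] = scores[mask].sum()
    return out


def classify_run(model: SWLDAModel, run_epochs: EpochSet, S: int,
                 roi: ROISpec | None = None) -> int:
    """Predicted stimulus id from the first S sequences of one run.

    Scores of each stimulus' epochs with sequence index <= S are summed and
    the argmax returned; ties are broken toward the lowest stimulus id
    (logged).  Zeroed epochs contribute the intercept only.
    """
    stimuli = sorted(run_epochs.info["stimulus_id"].unique())
    mat = sequence_scores(model, run_epochs, roi, stimuli)
    if not (1 <= S <= mat.shape[0]):
        raise ValueError(f"S={S} outside 1..{mat.shape[0]}")
    totals = mat[:S].sum(axis=0)
    best = int(np.argmax(totals))  # argmax returns the first maximum
    if (totals == totals[best]).sum() > 1:
        logger.info("score tie in classify_run; picking lowest stimulus id")
    return int(stimuli[best])


def stimuluswise_loocv(epochs: EpochSet, sound: int,
                       S: int | None = None,
                       roi: ROISpec | None = None,
                       swlda_config: SWLDAConfig | None = None,
                       zero_threshold: float = 80.0):
    """Leave-one-run-out accuracy for one sound.

    ``epochs`` is a subject's full preprocessed EpochSet (artifact flags set).
    The 10 runs in which ``sound`` was the target are selected; per fold the
    classifier is trained on the retained epochs of the other 9 runs (labels:
    epoch stimulus == sound) and the held-out run — with over-threshold test
    epochs zeroed — is classified for every sequence count.  Returns the
    accuracy vector over S = 1..n_sequences, or a scalar if ``S`` is given.
    """
    roi = roi or ROISpec()
    swlda_config = swlda_config or SWLDAConfig()
    info = epochs.info
    target_runs = sorted(info.loc[info["is_target"]
                                  & (info["stimulus_id"] == sound),
                                  "run_id"].unique())
    expected = 10
    n_seq = int(info["sequence_index"].max())
    if len(target_runs) != expected:
        raise ValueError(f"sound {sound} was target in {len(target_runs)} "
                         f"runs; expected {expected}")
    correct = np.zeros(n_seq, dtype=int)
    run_ids = info["run_id"].to_numpy()
    for held_out in target_runs:
        train_mask = np.isin(run_ids, [r for r in target_runs if r != held_out])
        train = epochs.select(train_mask).retained()
        # LOOCV hygiene: the held-out run must not appear in training.
        assert held_out not in set(train.info["run_id"]), "fold leakage"
        feats = roi_extract(train, roi)
        labels = (train.info["stimulus_id"] == sound).to_numpy()
        model = swlda_fit(feats, labels, swlda_config)
        test = zero_outlier_epochs(epochs.select(run_ids == held_out),
                                   zero_threshold)
        stimuli = sorted(test.info["stimulus_id"].unique())
        mat = sequence_scores(model, test, roi, stimuli)
        cum = np.cumsum(mat, axis=0)
        preds = [stimuli[int(np.argmax(row))] for row in cum]
        correct += np.asarray(preds) == sound
    acc = correct / len(target_runs)
    if S is not None:
        if not (1 <= S <= n_seq):
            raise ValueError(f"S={S} outside 1..{n_seq}")
        return float(acc[S - 1])
    return acc


def accuracy_curves(subject_epochs, roi: ROISpec | None = None,
                    swlda_config: SWLDAConfig | None = None,
                    zero_threshold: float = 80.0) -> AccuracyTable:
    """LOOCV accuracy for every subject x sound x sequence count.

    ``subject_epochs`` is an iterable of ``(subject_id, EpochSet)`` pairs (a
    dict works); subjects can be streamed to bound memory.
    """
    items = subject_epochs.items() if hasattr(subject_epochs, "items") \
        else subject_epochs
    rows = []
    for subject, epochs in items:
        sounds = sorted(epochs.info["stimulus_id"].unique())
        for sound in sounds:
            acc = stimuluswise_loocv(epochs, sound, None, roi, swlda_config,
                                     zero_threshold)
            for s_idx, a in enumerate(acc, start=1):
                rows.append((subject, sound, s_idx, float(a)))
    frame = pd.DataFrame(rows, columns=["subject", "stimulus", "S",
                                        "accuracy"])
    return AccuracyTable(frame=frame)


def rm_anova_two_way(table: AccuracyTable) -> pd.DataFrame:
    """Two-way repeated-measures ANOVA on the accuracy table.

    Within-subject factors: stimulus type and number of sequences.  For 18
    subjects and 5 sounds the main-effect dfs are (4, 68) and (9, 153).  No
    sphericity correction is applied so the dfs match that design arithmetic.
    Returns a frame with factor, df_num, df_den, F, p.
    """
    frame = table.frame
    counts = frame.groupby(["subject"]).size()
    if counts.nunique() != 1:
        raise ValueError("accuracy table is unbalanced or has missing cells")
    res = AnovaRM(frame, depvar="accuracy", subject="subject",
                  within=["stimulus", "S"]).fit()
    tab = res.anova_table.reset_index().rename(columns={
        "index": "factor", "F Value": "F", "Num DF": "df_num",
        "Den DF": "df_den", "Pr > F": "p"})
    tab["df_num"] = tab["df_num"].astype(int)
    tab["df_den"] = tab["df_den"].astype(int)
    return tab[["factor", "df_num", "df_den", "F", "p"]]


def posthoc_paired_t(wide: pd.DataFrame) -> pd.DataFrame:
    """Paired t-tests between all stimulus pairs across subjects.

    ``wide`` is a subject x stimulus accuracy matrix (e.g. from
    ``AccuracyTable.at_sequences``).  Both raw and Holm-adjusted p-values are
    reported.  Zero-variance differences are handled by convention: all-zero
    differences give p = 1 (no difference), a non-zero constant difference
    gives p = 0 (perfectly consistent direction); both are noted.
    """
    if wide.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    stimuli = list(wide.columns)
    rows = []
    for a, b in itertools.combinations(stimuli, 2):
        d = wide[a].to_numpy(dtype=float) - wide[b].to_numpy(dtype=float)
        note = ""
        if np.allclose(d.std(ddof=1), 0.0):
            if np.allclose(d, 0.0):
                tstat, p = 0.0, 1.0
                note = "identical columns"
            else:
                tstat = np.inf * np.sign(d.mean())
                p = 0.0
                note = "constant non-zero difference"
        else:
            tstat, p = stats.ttest_rel(wide[a], wide[b])
        rows.append((a, b, float(d.mean()), float(tstat), float(p), note))
    out = pd.DataFrame(rows, columns=["stimulus_a", "stimulus_b",
                                      "mean_diff", "t", "p_raw", "note"])
    out["p_holm"] = multipletests(out["p_raw"], method="holm")[1]
    return out[["stimulus_a", "stimulus_b", "mean_diff", "t",
                "p_raw", "p_holm", "note"]]
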