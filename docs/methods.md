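# Methods

This note documents the models and procedures implemented in `affectp300`,
the parameter choices that matter, and what the synthetic data can and
cannot tell you about real recordings.

## Synthetic EEG model

Each run's recording is a linear superposition of per-event evoked
templates plus additive noise, in microvolts at 256 Hz on the 8-channel
montage C3, Cz, C4, P3, Pz, P4, O1, O2 (mastoid-referenced by
construction; no re-referencing is performed).

**Evoked templates.** Every stimulus evokes two early exogenous components,
a negativity at 100 ms (Gaussian, σ = 20 ms, −4 µV at Cz) and a positivity
at 200 ms (σ = 25 ms, +3 µV at Cz), with a broad fronto-central scalp
weighting. Target stimuli additionally evoke a late P300-like positivity
peaking at 520 ms (σ = 70 ms) whose scalp weighting is maximal over
C3/Cz/C4 with parietal spill-over and little occipital share. Its amplitude
follows the thresholded-linear law

    A(v) = base + gain · max(0, |v| − threshold),

defaults base = 1.8 µV, gain = 1.8 µV per unit excess |valence|,
threshold = 1. With true valences (−2, −1, 0, +1, +2) only the ±2 sounds
are enhanced (3.6 µV vs 1.8 µV) — the ground truth the analysis is meant to
recover: a late-component boost that appears only beyond a valence
threshold, not in proportion to valence.

**Noise.** Per channel, an equal-variance mixture of white Gaussian noise
and 1/f-spectrum ("pink") noise, total sd 9 µV broadband, independent
across channels and runs. 1/f is the standard model of ongoing EEG
background; the pink fraction is configurable. There are no eye-blink or
EMG artifacts; an optional spike injector (`artifact_rate`,
`artifact_amp`) exists solely to exercise the 80 µV screens.

**Inter-subject variability.** A per-subject multiplicative amplitude
factor (uniform 0.8–1.2) and late-component latency shift (uniform
±30 ms), both reproducible from the seed.

**Run structure.** 2 parts × 5 sessions × 5 runs; within every session
each sound serves as target exactly once (a random permutation); within a
run the 50 events are 10 shuffled blocks of the 5 sounds at exactly 128
samples (500 ms) spacing, so each sound occurs once per sequence and the
per-sequence indexing of the score-sum classifier is well defined. One
second of signal pads the first and last onset.

**Calibration.** The paired defaults above were chosen once so that a
default 18-subject cohort reproduces the qualitative behaviour expected of
this paradigm: accuracy curves that rise with the number of sequences for
every sound, ±2-valence sounds far above the mid-valence sounds at S = 10
(≈ 0.95 vs ≈ 0.5), and exact chance (0.2) when the late component is
switched off. No per-subject empirical ERP statistics exist to fit, so the
defaults are representative, not estimated.

**Ratings.** For every subject and ordered pair (first i, second j) the
rating is round(clip(v_j − v_i + δ + ε, −3, +3)) with order effect
δ = 0.1 and ε ~ N(0, 0.6²). Positive means the second sound is more
positive. Clipping at ±3 compresses the extreme differences, which (being
a non-additive distortion) produces a small genuine combination effect in
the Scheffé ANOVA — a realistic feature, since bounded scales do the same
in real data. δ is set small and borderline-detectable on purpose.

## Preprocessing

Filtering is 6th-order Butterworth 0.1–20 Hz, implemented as second-order
sections and applied zero-phase (forward–backward) so the 400–700 ms ROI
is not latency-shifted; this doubles the effective order, and a causal
single pass is available via `zero_phase=False`. The filter is applied to
the continuous recording *before* epoching to avoid epoch-edge transients;
a regression test confirms this matches filtering widely-padded epochs
away from their edges.

Epochs are [−100, 800) ms, half-open, with the sample grid anchored at the
stimulus onset sample; the first sample is the one at or below −100 ms, so
the axis always covers −100…0 and 400…700 ms (230 samples at 256 Hz).
Baseline is the closed interval −100…0 ms. Epoch windows overlap (SOA
500 ms < 900 ms span) and are extracted independently.

The 80 µV amplitude screens use post-filter, post-baseline amplitudes
across all 8 channels and are strict ("exceeds"): a peak of exactly 80 µV
is retained. Training epochs are *rejected* (kept in place, excluded from
averages and fits); test epochs are *zeroed* (all samples set to 0), so a
contaminated test epoch contributes only the intercept to every stimulus'
score sum and cannot swing a classification.

The online-system feature chain (4-sample moving average, Savitzky-Golay
order 5 / window 81, decimation 256→64 Hz) is provided for parity but is
not part of the offline analysis, which keeps the raw sampling rate.

## Point-biserial maps

At every channel × time cell, r is the point-biserial correlation of
amplitude with the target/non-target class; σ is the *population* standard
deviation of the pooled sample, which makes r identical to the Pearson
correlation with a 0/1 label (property-tested to 1e−12). Significance is a
two-sided no-correlation t-test on N₂+N₁−2 df, Bonferroni-corrected over
all cells (8 × 230 = 1840 per map); non-surviving cells are reported as
r² = 0. The mask level is α = 0.05 (configurable and echoed in outputs).
Per sound, the target class is the sound's epochs from runs where it was
the counted target and the non-target class its epochs from all other
runs, pooled over both experiment parts; per-subject maps are averaged for
display.

## SWLDA

Classical stepwise regression of a 0/1 class code (target = 1): forward
step adds the excluded feature with the smallest partial-F p-value if
< p_in = 0.1; backward step removes the worst included feature if its
p-value > p_out = 0.15; repeat to a fixed point. p_in ≤ p_out prevents
entry/removal cycling; an iteration cap (20 × max_features) raises if ever
hit. Ties in the minimum p-value break toward the lowest feature index so
the fit is deterministic, and the result is invariant to epoch order. The
feature cap is 60, the customary SWLDA ceiling in the BCI literature; it
is configurable and surfaced in the model metadata. Zero-variance and
collinear candidates are skipped. Final weights are OLS on the selected
features; an empty model (nothing passes p_in) scores every epoch at the
intercept, i.e. the label mean, and is logged.

The implementation maintains an orthonormal basis of the current design
(modified Gram–Schmidt), so each forward sweep over all candidates is
O(n·p); a converged model is verified in tests to satisfy the fixed point
(no excluded feature could enter, none included should leave) against
independent statsmodels regressions.

## Stimulus-wise LOOCV and group statistics

ROI features are the raw-rate samples of C3, Cz, C4 in [400, 700) ms,
channel-major — 76 samples per channel, 228 features. The window is
half-open; the sample count is floor(window · fs), starting at the first
sample at or after the window onset.

For each sound: of the 10 runs where it was the target, each in turn is
held out; the classifier is trained on all retained epochs of the other 9
runs (450 epochs: 90 target, 360 non-target, before rejection) with labels
"epoch is this sound"; the held-out run — with its over-threshold epochs
zeroed — is classified for each S by the score-sum rule, ties toward the
lowest stimulus id (logged). Fold hygiene (held-out run absent from
training) is asserted in every fold. Accuracy per sound × S is
#correct/10.

Accuracy tables are compared with a two-way repeated-measures ANOVA
(within factors stimulus and S) via statsmodels AnovaRM; no sphericity
correction is applied by default so the dfs match the balanced design
arithmetic ((4, 68) and (9, 153) at 18 subjects). Post-hoc paired t-tests
over all 10 sound pairs report raw and Holm-adjusted p-values; zero-
variance difference vectors are reported as p = 1 when identically zero
(no difference) and p = 0 when a non-zero constant (perfectly consistent
direction), each with a note.

## Scheffé analysis, Ura's variation

With ratings y_{ij,k} (judge k, first i, second j; positive = second more
positive), the model is

    y_{ij,k} = (α_j − α_i) + γ_{ij} + δ + δ_k + ε_{ij,k},

γ antisymmetric (combination effect), δ the average order effect, δ_k its
per-judge deviation. Scale values are
α̂_i = [Σ y_{·i·} − Σ y_{i··}]/(2Nt), zero-sum by construction. The sum of
squares of the uncorrected total Σy² (df = N·t(t−1); δ plays the
grand-mean role) decomposes into main effect (df t−1), individual
difference of ratings ((t−1)(N−1)), combination ((t−1)(t−2)/2), average
order effect (1), individual order effect (N−1), and error (remainder; 264
at t = 5, N = 18); each factor is F-tested against the error mean square.
The decomposition is pinned by a brute-force least-squares oracle on the
full design matrix in the test suite.

All pairwise differences α̂_i − α̂_j share the yardstick half-width
Y = q(level; t, df_error) · √(MS_error/(2Nt)) with q the studentized-range
quantile (default level 0.99); a pair differs significantly iff its
interval excludes zero. Var(α̂_i) = σ²(t−1)/(2Nt²) ≈ σ²/(2Nt), which makes
the studentized-range calibration appropriate; under a null with equal
true valences, the any-significant-pair rate is ≈ 1% (Monte-Carlo tested).
Degenerate data (zero error variance) yield Y = 0 and point intervals.
The analysis accepts any real ratings in [−3, 3]; integer clipping is a
generator concern.

## Numerical and design choices

- Epoch/ROI window endpoints are half-open; "400–700 ms" keeps
  floor(0.3 s × 256 Hz) = 76 samples per channel.
- Stepwise p-values come from the partial F of the current residual
  (equivalently the squared t of the candidate in the augmented model), so
  forward and backward tests are mutually consistent.
- Label coding target = 1 / non-target = 0; any affine recoding rescales
  scores affinely and leaves rankings, hence classifications, unchanged.
- classify_run at S equals the argmax of the sum of the S independently
  computed per-sequence score vectors (tested), so partial-sequence
  analyses are consistent with the full rule.
- EDF output is plain 16-bit EDF with 1 s records, zero-padded to whole
  records, symmetric physical range chosen per file (~0.01 % quantization
  of peak); files are read back via `mne.io.read_raw_edf`, which doubles
  as an interoperability check on the writer.
- The chance-floor check uses a cluster-robust Monte-Carlo band over the
  90 (subject × sound) LOOCV cells: folds within a cell share 9 of 10
  training runs and are positively correlated, so a fold-level binomial
  band would be too narrow.

## Problem sizes used in tests and the acceptance script

Full-cohort computations use the complete default design — 18 subjects ×
50 runs × 50 epochs, stimulus-wise LOOCV for all 5 sounds × 10 folds ×
S = 1…10 — for both the default and the null (late component off)
generators; oracle suites use 100–1000 small randomized instances each.
The whole test suite runs in well under two minutes on one CPU.

## Limitations

- The generator's ERP templates are smooth Gaussians with fixed component
  latencies per subject; real ERPs have trial-to-trial latency jitter,
  non-Gaussian shapes, and condition-dependent early components.
- Noise is stationary, channel-independent 1/f + white; real EEG has
  spatially correlated background activity, alpha rhythms, blinks and EMG.
  Passing tests therefore demonstrate correctness of the analysis chain
  and recoverability of the embedded effect, not expected accuracy levels
  on real recordings.
- Ratings are generated without genuine per-judge preference differences,
  so the "individual difference of ratings" factor is null in simulation;
  real raters disagree.
- Only Ura's variation is implemented; Scheffé's original between-subjects
  design and the Nakaya/Haga variants are out of scope, as are ICA/
  regression artifact correction, channel interpolation, online feedback,
  and information-transfer-rate metrics.
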