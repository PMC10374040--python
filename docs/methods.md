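# Methods

`pausetrack` studies how inserting fixed silent pauses between the words of
continuous speech changes how well the speech envelope can be linearly
reconstructed from EEG ("cortical tracking"), using a backward multivariate
temporal response function (mTRF), i.e. a stimulus-reconstruction decoder.
This note documents the models, the numerical choices, and what the
synthetic data do and do not establish.

## The decoder

The decoder is a lagged linear map from multichannel EEG to the band-limited
speech envelope,

    S_hat(t) = sum_n sum_tau r(t + tau, n) g(tau, n),

with anticausal lags tau in 0–300 ms (variant 0–500 ms for the
pauses-removed analysis): the EEG *following* time t carries the response to
the stimulus at t.  Weights are the Tikhonov-regularized least-squares
solution

    g = (R'R + lambda M)^(-1) R'S,

where R is the time × (channels · lags) design built per channel block
(channel-major columns; samples beyond the recording end are zero-padded)
and M is a second-difference smoothness penalty across lags — tridiagonal
blocks with diagonal [1, 2, …, 2, 1] and off-diagonals −1, one block per
channel, with no cross-channel coupling.  M is applied unscaled; the lambda
grid (50 log-spaced points from 1e-2 to 1e12) spans enough orders of
magnitude that scaling conventions merely shift the selected index.

Numerical choices:

- Design columns and the target are mean-centered over the retained rows
  before solving; no intercept column is added (each penalty block has the
  constant vector in its null space, so an unpenalized intercept would be
  redundant and ill-conditioned).  Reconstruction is the pure linear form
  S_hat = R g; Pearson r is offset-invariant, so centering is harmless for
  the headline metric.
- Samples excluded by a feature mask (pauses, onsets-only, non-onsets-only)
  are removed from the normal equations and from scoring — exactly
  equivalent to physically deleting those rows, which the tests verify to
  1e-12.
- The single-fit solver is a symmetric positive-definite (Cholesky)
  factorization with a least-squares fallback.  The cross-validation path
  solves the entire lambda grid in one batched factorization from cached
  per-segment cross-products; it is numerically identical to the direct
  per-fold fit (verified to ~1e-9 in the tests).  At the smallest lambdas
  the lag columns of band-limited EEG are near-collinear and the normal
  equations can be numerically singular; those grid points fall back to a
  minimum-norm least-squares solve, and cross-validation penalizes them
  anyway.
- As lambda → ∞ the solution converges to the least-squares fit inside the
  penalty's null space (per-channel constants across lags), not to zero;
  g'Mg → 0 monotonically.  Only in the degenerate single-lag case (identity
  penalty block) does the weight vector itself vanish.

## Evaluation

Leave-one-out cross-validation over the (default four) speech segments of
one (subject, condition, band): train on the concatenated remaining
segments (per-segment designs; no lagged row spans a segment boundary),
score Pearson r and MSE on the held-out one, average the four fold scores
per lambda, and select the lambda with the highest mean r (ties go to the
smaller lambda).  Lambda is selected on the same cross-validated scores
that are reported; this induces a small optimism that is shared by all
cells and conditions.  Each train × test feature cell selects its own
lambda.  Decoders are trained on each of the three speech features (full
envelope, onsets, non-onsets) and tested on all three, giving the 3 × 3
grid; duration-matched variants truncate every segment to a fixed length
first, and the pauses-removed variant drops pause-labelled samples from
both the target and the design rows before fitting and scoring.

## Segmentation

Pauses are detected on the broadband envelope at the analysis rate (128 Hz)
— not on the band-passed envelope, which oscillates about zero and has no
stable zero level: samples below 1% of the envelope's 95th-percentile
amplitude for at least 100 ms are pauses.  Both constants are exposed in
configuration; the minimum duration keeps brief intra-word dips from
counting as pauses.  The onset region is the first 150 ms of speech after
each pause (19 samples at 128 Hz); everything else is non-onset.  The three
labels partition the time axis.  For synthetic data the mask can instead be
taken from generator ground truth (the default in the batch runner);
threshold detection is validated against that ground truth in the tests.

## Preprocessing and envelope extraction

EEG: common-average reference → zero-phase FIR band-pass (delta 1–4 Hz or
theta 4–8 Hz) → polyphase resampling to 128 Hz → per-channel z-normalization
with the population (1/N) standard deviation.  The filter is a
Hamming-window firwin design whose length is 6.6 times the reciprocal of
the shortest transition band; transition widths are 25% of each corner
frequency, floored at 2 Hz for the upper edge and capped at the lower
corner for the lower edge.  The stimulus envelope is the magnitude of the
analytic (Hilbert) signal of the waveform, band-passed with the same filter
contract and resampled to the same rate.  Modulation spectra are
unit-normalized Welch periodograms (4 s windows) of the broadband envelope
on 0–32 Hz, optionally after excising pause samples.

## Inference

Per-recording significance uses a permutation null: envelope–EEG pairings
are mismatched by a derangement of the segments (no envelope keeps its own
EEG) in both training and testing, the full cross-validation including
lambda selection is re-run, and the observed mean r is compared with the
empirical 95th-percentile (quantile type "higher", conservative for a
500-draw null) of 500 such draws (the calibration study in the tests uses
200).  With four segments there are only nine derangements — too few to
resolve a 95th-percentile critical value (the test would reject at a 10%
floor) — so below 20 derangements all non-identity permutations are used
(23 for n = 4); the CV value is computed once per distinct pairing and
sampled, identical in distribution to the naive loop.  All segments are
truncated to their common minimum length before the test: if mismatched
pairs were truncated while the matched pairing kept its full length, the
observed score would not be exchangeable with its null and the test would
be anti-conservative (verified empirically during development via the rank
of the observed score among all pairings).  Cohort comparisons use Friedman tests
across pause conditions and two-sided Wilcoxon signed-rank tests between
feature cells (zero differences dropped, mid-ranks for ties, exact p for
n ≤ 25 without ties, continuity-corrected normal approximation otherwise),
with Bonferroni-corrected significance levels.

## The synthetic-data generator

No public EEG accompanies this problem, so the generator produces paired
envelope/EEG data with the structure the analysis assumes.

Speech side: each word is an amplitude burst — a half-wave-rectified
sinusoid at the syllabic rate (default 4.5 Hz; one bump per syllable, small
positivity floor) under a 30 ms raised-cosine attack/decay — with word
durations lognormal (mean 0.35 s, sd 0.15 s) and natural inter-word gaps
lognormal (mean 80 ms, sd 40 ms; placeholders, exposed in config, as no
quantitative pause statistics are available for real narration).  The
deep syllabic modulation places the envelope modulation peak at 4–5 Hz;
inserting 250/500 ms silences between consecutive words (n_words − 1
insertions, none after the final word) adds a delta-band peak.  All
durations are rounded to whole samples so pause excision reproduces a
bit-identical concatenated stimulus across conditions.  Word sequences are
drawn per (subject, segment) and shared across conditions; noise per
(subject, segment, condition); all streams spawn from one master seed.

EEG side: each channel is

    onset_gain · (k_c ⊛ onset_drive) + sustained_gain · (k_c ⊛ envelope) + 1/f noise,

where the per-channel kernel k_c has a fast biphasic P1/N1-like component
(latency 110 ms ± 20 ms jitter, width 35 ms) plus a slow late positivity (a
P2/sustained-potential analogue: gain 0.4, +140 ms, width 110 ms) and a
random mixed-polarity gain.  The slow component matters: without it the
kernel carries no delta-band energy across a 500 ms pause, and the mid-pause
troughs of the delta envelope cannot be predicted within a 0–300 ms lag
window.  The onset drive is the envelope in the first 150 ms of speech after
each pause, scaled by 1 − exp(−pause/τ) with τ = 0.45 s — the
release-from-adaptation behaviour of the auditory late response, which is
the physiological mechanism proposed for pause-enhanced tracking.  Noise is
white Gaussian shaped by a fixed 8-second FIR with amplitude response
f^(−exponent/2) (power ∝ 1/f by default) — a *stationary* process whose
distribution does not depend on segment length, which the permutation
test's exchangeability requires (FFT-synthesized noise at each segment's own
length would tie each EEG's distribution to its matched envelope's
duration).  Its amplitude is a
property of the subject, not of the stimulus: it is calibrated per
(subject, segment, channel) so that the *natural* condition sits at
`snr_db`, and that same absolute level is reused for the pause-inserted
conditions (background EEG does not get louder because evoked responses
do).  The default onset gain is a nominal 10× the sustained gain; because
of adaptation the *effective* onset dominance is ≈ 1.6× in natural speech
(80 ms gaps) and ≈ 5–7× in the pause conditions — an onset-dominant
regime.  Under this model the onset-dominance pattern (full-trained
decoders score higher on onsets than non-onsets) and the monotone increase
of full-envelope r from natural to short to long pauses both emerge across
a broad noise range (≈ −10 to −16 dB; the study default is −12 dB).

What the generator does **not** emulate: phonetics and linguistic
boundaries, ocular/muscle artifacts, inter-trial attention drift,
non-linear or adaptive encoding beyond the single recovery factor, and
spatially correlated noise.  Passing tests therefore show that the
*analysis pipeline* behaves correctly and that the reported qualitative
patterns follow from an onset-dominant linear response model with
adaptation — they do not certify effect sizes in real EEG.

## Problem sizes

Analyses run directly at the 128 Hz analysis rate with desk-scale cohorts:
the cohort study uses 16 subjects × 3 conditions × 2 bands with 4 segments
of 120 words (≈ 50 s natural speech) and 8 EEG channels; noiseless recovery
uses 4 × 2-minute segments; permutation calibration uses 200 null datasets
of 4 × ≈20 s segments at 2 channels with 200 permutations each.  The
full-scale configuration of the emulated experiment (32 channels, 4092 Hz
acquisition, ~150 s segments, 500 permutations) is the generator default
and runs through exactly the same code paths.

## Known limitations

- The acquisition rate is taken at face value as 4092 Hz (configurable);
  hardware convention would suggest 4096 Hz.
- Whether lambda should be re-selected inside each permutation is an open
  interpretive question; it is re-selected here (conservative), switchable.
- MSE is reported on the raw linear reconstruction R g; because targets are
  band-passed (≈ zero-mean) and the EEG z-normalized, the omitted intercept
  is negligible, but MSE is not offset-corrected.
- Real-audio alignment (word boundaries) must be supplied externally; no
  forced aligner is included.
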