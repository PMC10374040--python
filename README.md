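# pausetrack

Cortical tracking of continuous speech under inserted silent pauses:
stimulus manipulation, speech-envelope extraction, backward-mTRF
(stimulus-reconstruction) decoding from EEG, cross-validated evaluation,
and nonparametric inference — with a synthetic speech-envelope/EEG
generator so the entire analysis runs end-to-end with known ground truth.

## The problem

When fixed silences (250 ms or 500 ms) are spliced between the words of a
narrated story, EEG reconstruction of the speech envelope improves — a
phenomenon attributed to strong evoked responses at acoustic onsets
following silence.  This package implements that analysis for anyone
studying envelope tracking: auditory neuroscientists, hearing researchers,
and methodologists who need a tested reference implementation.

The core model is the backward multivariate temporal response function
(mTRF).  The decoder g(τ, n) reconstructs the band-limited envelope S from
EEG r over anticausal lags τ (0–300 ms) and channels n,

    Ŝ(t) = Σₙ Στ r(t + τ, n) g(τ, n),
    g = (RᵀR + λM)⁻¹ RᵀS,

with R the lagged design and M a per-channel second-difference smoothness
penalty (tridiagonal, diagonal [1, 2, …, 2, 1], off-diagonals −1).  λ is
chosen from 50 log-spaced values in [10⁻², 10¹²] by leave-one-out
cross-validation over speech segments; performance is the fold-averaged
Pearson r between Ŝ and S.  Decoders are trained and tested on three
speech features — the full envelope, onset regions (first 150 ms of speech
after each pause), and non-onsets — in the delta (1–4 Hz) and theta
(4–8 Hz) bands.  Per-recording significance comes from a permutation null
(mismatched envelope–EEG pairings, full CV re-run); cohort comparisons use
Friedman and Wilcoxon signed-rank tests with Bonferroni correction.

See `docs/methods.md` for the full model description and numerical choices.

## Worked example

```python
import dataclasses
from pausetrack import (SimConfig, CVPlan, LagSpec, simulate_segment,
                        segments_from_records, run_cv)

cfg = SimConfig(n_channels=8, fs_eeg=128.0, fs_env=128.0,
                n_words_per_segment=120, onset_gain=10.0,
                sustained_gain=1.0, snr_db=-12.0, seed=104)

for cond in ("natural", "short", "long"):
    records = [simulate_segment(cfg, cond, subject=0, segment=s)
               for s in range(4)]
    segments = segments_from_records(records, band="delta")
    plan = CVPlan(segments=segments, lag_spec=LagSpec(0, 300, 128),
                  condition=cond, band="delta")
    res = run_cv(plan)
    print(f"{cond:8s} mean r = {res.mean_r:.3f} "
          f"(lambda = {res.selected_lambda:.3g})")
```

prints

```
natural  mean r = 0.646 (lambda = 1e+04)
short    mean r = 0.752 (lambda = 7.2)
long     mean r = 0.793 (lambda = 13.9)
```

Reconstruction accuracy increases as longer pauses are inserted: the
envelope of speech with pauses is better reconstructed from the simulated
EEG, because onset responses (enhanced after longer silences) dominate the
recording.  The selected λ is the regularization weight that maximized the
cross-validated fold-averaged correlation.

A single decoder fit is also available statsmodels-style:

```python
from pausetrack import EnvelopeDecoder
model = EnvelopeDecoder(segments[0].envelope, segments[0].eeg)
results = model.fit(lam=100.0)
print(results.summary())
r, mse = results.evaluate(segments[1].envelope, segments[1].eeg)
```

The full study (all subjects, conditions, bands, the 3×3 train/test
feature grid, statistics and figures) is driven by a YAML config:

```sh
pausetrack run --config study.yaml --out results/
pausetrack simulate --config sim.yaml --out fixture/
pausetrack stimulus insert-pauses --pause-ms 250 in.wav words.tsv out.wav
```

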