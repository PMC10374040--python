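"""Segmentation of the envelope time axis into pauses, onsets and non-onsets.

A pause is a run of near-zero broadband envelope (at the analysis rate)
lasting at least ``min_pause_ms``; the onset region is the first
``onset_window_ms`` (default 150 ms) of speech following each pause; all
remaining speech is non-onset.  The labels partition the time axis, and the
resulting masks are applied to the band-limited envelope features that the
decoder is trained and scored on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd

from .datatypes import EEGRecording, EnvelopeSeries, FEATURES

__all__ = [
    "PAUSE", "ONSET", "NON_ONSET", "SegmentMask",
    "detect_pauses", "mask_from_intervals", "build_feature",
    "remove_pause_samples", "amplitude_histogram",
]

PAUSE, ONSET, NON_ONSET = 0, 1, 2
_LABEL_NAMES = {PAUSE: "pause", ONSET: "onset", NON_ONSET: "non_onset"}


@dataclass
class SegmentMask:
    """Per-sample labels over the envelope time axis."""

    labels: np.ndarray  # int8, values in {PAUSE, ONSET, NON_ONSET}
    fs: float
    onset_window_ms: float = 150.0
    threshold: float = 0.0
    min_pause_ms: float = 100.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if not np.all(np.isin(self.labels, [PAUSE, ONSET, NON_ONSET])):
            raise ValueError("labels must be pause/onset/non_onset codes")

    @property
    def n_samples(self) -> int:
        return self.labels.size

    def counts(self) -> Dict[str, int]:
        return {name: int(np.sum(self.labels == code))
                for code, name in _LABEL_NAMES.items()}

    def to_intervals(self) -> pd.DataFrame:
        """BED-like table of labelled intervals (start_s, end_s, label)."""
        lab = self.labels
        change = np.flatnonzero(np.diff(lab)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [lab.size]])
        return pd.DataFrame({
            "start_s": starts / self.fs,
            "end_s": ends / self.fs,
            "label": [_LABEL_NAMES[int(lab[s])] for s in starts],
        })


def _label_onsets(speech: np.ndarray, fs: float, onset_window_ms: float
                  ) -> np.ndarray:
    """Given a boolean speech mask, label the first onset_window of each
    speech run that follows a pause run as ONSET."""
    labels = np.full(speech.size, PAUSE, dtype=np.int8)
    labels[speech] = NON_ONSET
    win = int(round(onset_window_ms / 1000.0 * fs))
    d = np.diff(speech.astype(int))
    run_starts = list(np.flatnonzero(d == 1) + 1)  # speech runs preceded by pause
    for s in run_starts:
        e = s
        n = speech.size
        stop = min(s + win, n)
        while e < stop and speech[e]:
            e += 1
        labels[s:e] = ONSET
    return labels


def detect_pauses(env: EnvelopeSeries, threshold_frac: float = 0.01,
                  min_pause_ms: float = 100.0,
                  onset_window_ms: float = 150.0) -> SegmentMask:
    """Threshold-based pause detection on the broadband envelope at the
    analysis rate.

    The threshold is ``threshold_frac`` of the envelope's 95th-percentile
    amplitude ("a low threshold level around the zero value"); sub-threshold
    runs of at least ``min_pause_ms`` are pauses.  Onset/non-onset labels are
    then assigned relative to the detected pauses.
    """
    if not (0.0 < threshold_frac < 1.0):
        raise ValueError("threshold_frac must be in (0, 1)")
    if env.band != "broadband":
        raise ValueError("pause detection runs on the broadband envelope")
    x = env.values
    thr = threshold_frac * np.percentile(x, 95)
    below = x <= thr
    min_run = max(int(round(min_pause_ms / 1000.0 * env.fs)), 1)

    # keep only sub-threshold runs of sufficient length as pauses
    pause = np.zeros(x.size, dtype=bool)
    d = np.diff(below.astype(int))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if below.size and below[0]:
        starts.insert(0, 0)
    if below.size and below[-1]:
        ends.append(below.size)
    for s, e in zip(starts, ends):
        if e - s >= min_run:
            pause[s:e] = True

    labels = _label_onsets(~pause, env.fs, onset_window_ms)
    return SegmentMask(labels=labels, fs=env.fs, onset_window_ms=onset_window_ms,
                       threshold=float(thr), min_pause_ms=min_pause_ms)


def mask_from_intervals(pause_intervals: Sequence[Tuple[float, float]],
                        n_samples: int, fs: float,
                        onset_window_ms: float = 150.0) -> SegmentMask:
    """Build the label mask from known (ground-truth) pause intervals instead
    of threshold detection — available for synthetic data."""
    speech = np.ones(n_samples, dtype=bool)
    for ps, pe in pause_intervals:
        speech[int(round(ps * fs)):int(round(pe * fs))] = False
    labels = _label_onsets(speech, fs, onset_window_ms)
    return SegmentMask(labels=labels, fs=fs, onset_window_ms=onset_window_ms,
                       min_pause_ms=0.0)


def build_feature(env: EnvelopeSeries, mask: SegmentMask,
                  feature: str) -> EnvelopeSeries:
    """Attach the validity mask selecting one speech feature.

    ``full``: every sample valid (onsets, non-onsets and pauses).
    ``onsets``: only onset-labelled samples valid.
    ``non_onsets``: only non-onset-labelled samples valid.
    Excluded samples are omitted from decoder fitting and scoring.
    """
    if feature not in FEATURES:
        raise ValueError(f"feature must be one of {FEATURES}, got {feature!r}")
    if mask.n_samples != env.n_samples:
        raise ValueError("mask and envelope lengths differ")
    if feature == "full":
        valid = np.ones(env.n_samples, dtype=bool)
    elif feature == "onsets":
        valid = mask.labels == ONSET
    else:
        valid = mask.labels == NON_ONSET
    return env.with_mask(valid, provenance=feature)


def remove_pause_samples(env: EnvelopeSeries, eeg: EEGRecording,
                         mask: SegmentMask) -> Tuple[EnvelopeSeries, EEGRecording]:
    """Physically drop pause-labelled samples from both the envelope and the
    EEG at the same sample indices, concatenating the speech regions.

    In the decoder this deletion is applied to the rows of the lagged design
    (the lagged EEG time series) at the pause indices of the target, which is
    what :func:`pausetrack.evaluation.run_cv` does when asked for the
    pauses-removed analysis; this standalone form returns the shortened,
    index-aligned series.
    """
    if env.n_samples != eeg.n_samples:
        raise ValueError("envelope and EEG lengths differ")
    keep = mask.labels != PAUSE
    new_env = EnvelopeSeries(values=env.values[keep], fs=env.fs, band=env.band,
                             valid=env.valid[keep] if env.valid is not None else None,
                             provenance="pauses_removed")
    new_eeg = eeg.copy_with(data=eeg.data[:, keep])
    return new_env, new_eeg


def amplitude_histogram(env: EnvelopeSeries, mask: SegmentMask,
                        bins: int = 40) -> Dict[str, dict]:
    """Histograms of sample amplitudes for the onset and non-onset classes of
    a band-limited envelope (a balance diagnostic: the two classes should
    span similar amplitude ranges, while non-onsets contain more samples)."""
    if mask.n_samples != env.n_samples:
        raise ValueError("mask and envelope lengths differ")
    out: Dict[str, dict] = {}
    sel = {"onset": env.values[mask.labels == ONSET],
           "non_onset": env.values[mask.labels == NON_ONSET]}
    present = np.concatenate([v for v in sel.values() if v.size]) if any(
        v.size for v in sel.values()) else np.array([])
    if present.size == 0:
        raise ValueError("no onset or non-onset samples to histogram")
    edges = np.histogram_bin_edges(present, bins=bins)
    for name, vals in sel.items():
        counts, _ = np.histogram(vals, bins=edges)
        out[name] = {
            "counts": counts,
            "bin_edges": edges,
            "n_samples": int(vals.size),
            "amplitude_range": (float(vals.min()), float(vals.max())) if vals.size else None,
            "empty": vals.size == 0,
        }
    return out
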