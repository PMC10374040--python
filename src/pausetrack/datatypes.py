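"""Shared data containers for the speech-envelope / EEG decoding pipeline.

These are thin, validated wrappers around numpy arrays.  They carry the
metadata the analysis needs to stay honest about sampling rates, frequency
bands and sample-exclusion masks, but deliberately do nothing clever: all
signal processing lives in the stage modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np

BANDS = {"broadband": (None, None), "delta": (1.0, 4.0), "theta": (4.0, 8.0)}
FEATURES = ("full", "onsets", "non_onsets")
CONDITIONS = ("natural", "short", "long")

#: inserted silent pause per condition, seconds
CONDITION_PAUSE_S = {"natural": 0.0, "short": 0.25, "long": 0.5}


@dataclass
class AnnotatedAudio:
    """A speech waveform plus word-boundary annotations.

    Parameters
    ----------
    samples : 1-D float array, dimensionless amplitude in [-1, 1].
    fs : sampling rate in Hz.
    word_boundaries : sequence of (onset_s, offset_s) pairs, sorted and
        non-overlapping.  Contractions count as a single word when the
        annotation table is parsed.
    condition_label : one of ``natural``, ``short``, ``long``, ``other``.
    """

    samples: np.ndarray
    fs: float
    word_boundaries: Sequence[Tuple[float, float]] = field(default_factory=list)
    condition_label: str = "other"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("audio samples must be one-dimensional")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        bounds = [tuple(map(float, b)) for b in self.word_boundaries]
        dur = self.duration_s
        prev_off = -np.inf
        for on, off in bounds:
            if off <= on:
                raise ValueError(f"word boundary ({on}, {off}) has non-positive length")
            if on < prev_off - 1e-9:
                raise ValueError("word boundaries overlap or are unsorted")
            if on < -1e-9 or off > dur + 1e-6:
                raise ValueError("word boundary outside the recording")
            prev_off = off
        self.word_boundaries = bounds

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    @property
    def n_words(self) -> int:
        return len(self.word_boundaries)


@dataclass
class EnvelopeSeries:
    """An amplitude envelope, broadband or band-limited, with an optional
    validity mask.

    ``values`` is nonnegative for ``band='broadband'`` (magnitude of the
    analytic signal) and signed otherwise (band-passed).  ``valid`` marks the
    samples that participate in model fitting and scoring; excluded samples
    (pauses, or samples outside the selected speech feature) stay in the
    array so that the time axis is preserved, mirroring a NaN-exclusion
    convention without destroying alignment.
    """

    values: np.ndarray
    fs: float
    band: str = "broadband"
    valid: Optional[np.ndarray] = None
    provenance: str = "full"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("envelope must be one-dimensional")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.band not in BANDS:
            raise ValueError(f"unknown band {self.band!r}; expected one of {sorted(BANDS)}")
        if self.band == "broadband" and self.values.size and np.nanmin(self.values) < -1e-9:
            raise ValueError("broadband envelope must be nonnegative")
        if self.valid is not None:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.values.shape:
                raise ValueError("mask length must equal envelope length")

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return self.values.size / self.fs

    def valid_mask(self) -> np.ndarray:
        """Boolean validity mask (all-valid when no mask is attached)."""
        if self.valid is None:
            return np.ones(self.values.size, dtype=bool)
        return self.valid

    def with_mask(self, valid: np.ndarray, provenance: str) -> "EnvelopeSeries":
        return replace(self, valid=np.asarray(valid, dtype=bool), provenance=provenance)


@dataclass
class EEGRecording:
    """Multichannel EEG at one sampling rate.

    ``data`` is channels x samples; microvolts when raw, z-units after
    normalization.  Identifiers track provenance through the batch runner.
    """

    data: np.ndarray
    fs: float
    channel_names: Optional[Sequence[str]] = None
    subject_id: str = "S00"
    segment_id: int = 0
    condition_label: str = "other"
    band: str = "broadband"

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("EEG contains non-finite samples")
        if self.channel_names is None:
            self.channel_names = [f"CH{i:02d}" for i in range(self.data.shape[0])]
        else:
            self.channel_names = list(self.channel_names)
            if len(self.channel_names) != self.data.shape[0]:
                raise ValueError("channel_names length must match channel count")
        if self.band not in BANDS:
            raise ValueError(f"unknown band {self.band!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, **kwargs) -> "EEGRecording":
        return replace(self, **kwargs)
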