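"""EEG preprocessing: common-average reference, zero-phase FIR band-pass,
resampling to the analysis rate, and per-channel z-normalization.

Filter design follows the MNE "firwin" convention: a Hamming-windowed
linear-phase FIR whose length is 6.6 times the reciprocal of the shortest
transition band, applied with group-delay compensation so the net phase is
zero.  Transition bandwidths default to 25% of each corner frequency, with
the lower transition capped at the lower corner itself and the upper floored
at 2 Hz.  The delta band is 1-4 Hz, theta 4-8 Hz.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Tuple

import numpy as np
from mne.filter import filter_data
from scipy import signal

from .datatypes import BANDS, EEGRecording, EnvelopeSeries

__all__ = [
    "band_edges",
    "fir_bandpass",
    "rereference_common_average",
    "bandpass_eeg",
    "resample_eeg",
    "normalize_eeg",
    "preprocess_eeg",
]

#: default analysis rate after resampling, Hz
ANALYSIS_FS = 128.0


def band_edges(band: str) -> Tuple[float, float]:
    if band not in BANDS or band == "broadband":
        raise ValueError(f"band must be 'delta' or 'theta', got {band!r}")
    return BANDS[band]


def fir_bandpass(data: np.ndarray, fs: float, band: str) -> np.ndarray:
    """Zero-phase FIR band-pass shared by the EEG and envelope paths.

    ``data`` is (..., n_samples).  Raises if the recording is shorter than
    the filter the length rule demands.
    """
    lo, hi = band_edges(band)
    if hi >= fs / 2:
        raise ValueError(f"upper band edge {hi} Hz >= Nyquist of fs={fs}")
    return filter_data(np.ascontiguousarray(data, dtype=np.float64), sfreq=fs,
                       l_freq=lo, h_freq=hi, method="fir", phase="zero",
                       fir_window="hamming", fir_design="firwin",
                       verbose="error")


def rereference_common_average(eeg: EEGRecording) -> EEGRecording:
    """Subtract the instantaneous mean across channels from every channel."""
    if eeg.n_channels < 2:
        raise ValueError("common-average reference needs at least 2 channels")
    data = eeg.data - eeg.data.mean(axis=0, keepdims=True)
    return eeg.copy_with(data=data)


def bandpass_eeg(eeg: EEGRecording, band: str) -> EEGRecording:
    if eeg.band != "broadband":
        raise ValueError("band-pass expects broadband input")
    data = fir_bandpass(eeg.data, eeg.fs, band)
    return eeg.copy_with(data=data, band=band)


def resample_signal(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Polyphase resampling along the last axis."""
    if fs_out <= 0:
        raise ValueError("output rate must be positive")
    if fs_out == fs_in:
        return np.asarray(x, dtype=float).copy()
    frac = Fraction(fs_out / fs_in).limit_denominator(10000)
    # line-padding keeps edges sensible for constant/trending signals
    return signal.resample_poly(x, frac.numerator, frac.denominator, axis=-1,
                                padtype="line")


def resample_eeg(eeg: EEGRecording, fs_out: float = ANALYSIS_FS) -> EEGRecording:
    return eeg.copy_with(data=resample_signal(eeg.data, eeg.fs, fs_out), fs=fs_out)


def normalize_eeg(eeg: EEGRecording) -> EEGRecording:
    """Scale each channel to zero mean and unit (population, 1/N) standard
    deviation over the whole recording."""
    mean = eeg.data.mean(axis=1, keepdims=True)
    sd = eeg.data.std(axis=1, keepdims=True)  # population convention
    bad = np.flatnonzero(sd.ravel() == 0)
    if bad.size:
        names = [eeg.channel_names[i] for i in bad]
        raise ValueError(f"zero-variance channel(s): {names}")
    return eeg.copy_with(data=(eeg.data - mean) / sd)


def preprocess_eeg(eeg: EEGRecording, band: str,
                   fs_out: float = ANALYSIS_FS) -> EEGRecording:
    """Full chain: common-average reference -> band-pass -> resample ->
    z-normalize.  Deterministic; order follows the acquisition-to-analysis
    convention (filter before resampling)."""
    out = rereference_common_average(eeg)
    out = bandpass_eeg(out, band)
    out = resample_eeg(out, fs_out)
    return normalize_eeg(out)
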