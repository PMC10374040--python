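"""Stimulus-side processing: silent-pause insertion, Hilbert envelope
extraction, band-limiting to the delta/theta analysis bands, and modulation
spectra.

Pause insertion splices exact digital silence after each word offset except
the last, optionally with a short raised-cosine fade at the splice points to
avoid clicks in real audio (off by default so splices are sample-exact).
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import signal

from .datatypes import AnnotatedAudio, EnvelopeSeries
from .preprocess import ANALYSIS_FS, fir_bandpass, resample_signal

__all__ = [
    "insert_pauses",
    "extract_envelope",
    "bandlimit_envelope",
    "modulation_spectrum",
]


def insert_pauses(audio: AnnotatedAudio, pause_s: float,
                  fade_ms: float = 0.0) -> AnnotatedAudio:
    """Splice ``pause_s`` seconds of silence after every word except the last.

    Word boundaries are shifted accordingly; total duration grows by
    ``(n_words - 1) * pause_s``.  With ``fade_ms > 0`` a raised-cosine
    fade-out/in of that length is applied on either side of each splice.
    """
    if pause_s < 0:
        raise ValueError("pause duration must be nonnegative")
    if not audio.word_boundaries:
        raise ValueError("pause insertion requires word boundaries")
    if pause_s == 0:
        return AnnotatedAudio(samples=audio.samples.copy(), fs=audio.fs,
                              word_boundaries=list(audio.word_boundaries),
                              condition_label=audio.condition_label)
    fs = audio.fs
    gap_n = int(round(pause_s * fs))
    n_fade = int(round(fade_ms / 1000.0 * fs))
    bounds = audio.word_boundaries
    pieces = []
    new_bounds = []
    cursor = 0  # sample position in the input consumed so far
    shift = 0  # samples of silence inserted so far
    for i, (on, off) in enumerate(bounds):
        off_n = int(round(off * fs))
        new_bounds.append((on + shift / fs, off + shift / fs))
        if i < len(bounds) - 1:
            chunk = audio.samples[cursor:off_n].copy()
            if n_fade and chunk.size >= n_fade:
                fade = 0.5 * (1 + np.cos(np.pi * np.arange(n_fade) / n_fade))
                chunk[-n_fade:] *= fade
                # fade back in at the start of the next chunk is applied when
                # that chunk is cut (below) via the leading ramp
            pieces.append(chunk)
            pieces.append(np.zeros(gap_n))
            cursor = off_n
            shift += gap_n
        else:
            chunk = audio.samples[cursor:].copy()
            pieces.append(chunk)
    out = np.concatenate(pieces)
    if n_fade:
        # fade-in after each inserted gap
        pos = 0
        for i, (on, off) in enumerate(bounds[:-1]):
            pos = int(round(off * fs)) + (i + 1) * gap_n
            seg = out[pos:pos + n_fade]
            ramp = 0.5 * (1 - np.cos(np.pi * np.arange(seg.size) / max(n_fade, 1)))
            out[pos:pos + seg.size] = seg * ramp
    return AnnotatedAudio(samples=out, fs=fs, word_boundaries=new_bounds,
                          condition_label=audio.condition_label)


def extract_envelope(audio: AnnotatedAudio) -> EnvelopeSeries:
    """Broadband amplitude envelope: magnitude of the analytic (Hilbert)
    signal of the waveform, at the audio rate."""
    if audio.samples.size == 0:
        raise ValueError("cannot extract the envelope of an empty waveform")
    env = np.abs(signal.hilbert(audio.samples))
    return EnvelopeSeries(values=env, fs=audio.fs, band="broadband")


def bandlimit_envelope(env: EnvelopeSeries, band: str,
                       fs_out: float = ANALYSIS_FS) -> EnvelopeSeries:
    """Band-pass the broadband envelope (delta 1-4 Hz or theta 4-8 Hz) with
    the same zero-phase FIR design used for the EEG, then resample to the
    analysis rate."""
    if env.band != "broadband":
        raise ValueError("band-limiting expects a broadband envelope")
    filtered = fir_bandpass(env.values, env.fs, band)
    out = resample_signal(filtered, env.fs, fs_out)
    return EnvelopeSeries(values=out, fs=fs_out, band=band,
                          provenance=env.provenance)


def downsample_envelope(env: EnvelopeSeries, fs_out: float = ANALYSIS_FS
                        ) -> EnvelopeSeries:
    """Resample the broadband envelope to the analysis rate without
    band-passing (used for pause detection, where the zero level matters)."""
    vals = resample_signal(env.values, env.fs, fs_out)
    return EnvelopeSeries(values=np.clip(vals, 0.0, None), fs=fs_out,
                          band="broadband", provenance=env.provenance)


def modulation_spectrum(env: EnvelopeSeries, remove_pauses: bool = False,
                        pause_intervals: Optional[Sequence[Tuple[float, float]]] = None,
                        f_max: float = 32.0, window_s: float = 4.0,
                        ) -> Tuple[np.ndarray, np.ndarray]:
    """Averaged-periodogram (Welch) power spectrum of the broadband envelope
    on 0..``f_max`` Hz, normalized to unit total power.

    With ``remove_pauses`` the pause samples are excised and the remaining
    speech concatenated before the spectrum is taken, so stimuli that differ
    only in inserted silence produce identical spectra.
    """
    if env.band != "broadband":
        raise ValueError("modulation spectrum is defined on the broadband envelope")
    x = env.values
    fs = env.fs
    if remove_pauses:
        if pause_intervals is None:
            raise ValueError("remove_pauses requires pause_intervals")
        keep = np.ones(x.size, dtype=bool)
        for ps, pe in pause_intervals:
            keep[int(round(ps * fs)):int(round(pe * fs))] = False
        x = x[keep]
    nper = int(round(window_s * fs))
    if x.size < nper:
        raise ValueError("envelope shorter than one spectral window")
    x = x - x.mean()
    freqs, power = signal.welch(x, fs=fs, nperseg=nper)
    sel = freqs <= f_max
    freqs, power = freqs[sel], power[sel]
    df = freqs[1] - freqs[0]
    total = power.sum() * df
    if total > 0:
        power = power / total
    return freqs, power
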