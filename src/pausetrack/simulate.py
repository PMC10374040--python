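"""Synthetic paired speech-envelope / EEG data with known ground truth.

The generator emulates the structure of a listening experiment in which a
continuous story is presented either as recorded ("natural") or with fixed
silent pauses (250 ms "short", 500 ms "long") spliced between words, while
multichannel EEG is recorded.

The speech side is modelled at the envelope level only: each word is an
amplitude burst — a rectified sinusoid at the syllabic rate (default 4.5 Hz,
which places the envelope modulation peak in the 4–5 Hz range) under a
raised-cosine attack/decay contour — separated by short natural pauses, with
the condition's inserted silence added between consecutive words
(``n_words - 1`` insertions; no trailing pause).

The EEG side is a linear evoked-response model: each channel is the
convolution of a channel-specific response kernel with an *onset drive* (the
envelope restricted to the first 150 ms of speech after each pause) plus the
same kernel convolved with the full envelope (sustained drive), at gains
``onset_gain`` and ``sustained_gain``, buried in 1/f background noise scaled
to a per-channel SNR.  All randomness is drawn from per-(subject, segment,
condition) streams spawned from one master seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal

from .datatypes import CONDITIONS, CONDITION_PAUSE_S, EEGRecording, EnvelopeSeries
from . import io as ptio

__all__ = [
    "KernelSpec",
    "SimConfig",
    "GroundTruth",
    "SimRecord",
    "SyntheticDataset",
    "simulate_envelope",
    "simulate_eeg",
    "simulate_segment",
    "simulate_dataset",
    "write_fixture",
    "read_fixture",
]

#: duration of the post-pause onset window driving the evoked response, seconds
ONSET_WINDOW_S = 0.150


@dataclass
class KernelSpec:
    """Shape of the per-channel evoked-response kernel.

    The kernel has two components: a fast biphasic difference of Gaussians
    (a P1/N1-like deflection) at ``latency_ms`` with temporal scale
    ``width_ms``, and a slower late positivity (a P2/sustained-potential
    analogue) ``slow_latency_ms`` after the fast peak with gain
    ``slow_gain``.  The slow component is what carries delta-band response
    energy across silent gaps.  Channels differ by a random gain (mixed
    polarity, as scalp topographies reverse sign) and a random latency
    jitter, so the channel ensemble is informative enough for the decoder
    to invert.
    """

    latency_ms: float = 110.0
    width_ms: float = 35.0
    latency_jitter_ms: float = 20.0
    gain_mean: float = 0.8
    gain_sd: float = 0.6
    slow_gain: float = 0.4
    slow_latency_ms: float = 140.0
    slow_width_ms: float = 110.0
    duration_ms: float = 700.0


@dataclass
class SimConfig:
    """Study-level configuration for the synthetic cohort.

    Defaults mirror the experimental conditions being emulated: 16 subjects,
    4 segments per pause condition, 32-channel EEG acquired at 4092 Hz, words
    at a 4.5 Hz syllabic rate, inserted pauses of 0 / 250 / 500 ms.  The
    envelope itself is synthesized at ``fs_env`` (an intermediate rate; no
    audio-band carrier is modelled).
    """

    n_subjects: int = 16
    n_segments_per_condition: int = 4
    n_channels: int = 32
    fs_audio: float = 44100.0
    fs_eeg: float = 4092.0
    fs_env: float = 128.0
    n_words_per_segment: int = 350
    word_duration_mean: float = 0.35
    word_duration_sd: float = 0.15
    natural_pause_mean: float = 0.08
    natural_pause_sd: float = 0.04
    syllable_rate_hz: float = 4.5
    attack_decay_ms: float = 30.0
    lead_silence_s: float = 0.2
    trail_silence_s: float = 0.2
    kernel_spec: KernelSpec = field(default_factory=KernelSpec)
    onset_gain: float = 10.0
    sustained_gain: float = 1.0
    onset_recovery_tau_s: float = 0.45
    noise_exponent: float = 1.0
    snr_db: float = 0.0
    noise_reference: str = "natural"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("word_duration_mean", "word_duration_sd", "natural_pause_mean",
                     "fs_audio", "fs_eeg", "fs_env", "syllable_rate_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.natural_pause_sd < 0:
            raise ValueError("natural_pause_sd must be nonnegative")
        if self.n_segments_per_condition < 2:
            raise ValueError("need at least 2 segments per condition for leave-one-out CV")
        if self.n_words_per_segment < 2:
            raise ValueError("need at least 2 words per segment")
        if self.n_channels < 1 or self.n_subjects < 1:
            raise ValueError("channel and subject counts must be positive")
        if self.noise_reference not in ("natural", "self"):
            raise ValueError("noise_reference must be 'natural' or 'self'")

    def rng(self, *spawn_key: int) -> np.random.Generator:
        """RNG stream derived from the master seed by a spawn-key counter."""
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=spawn_key))


@dataclass
class GroundTruth:
    """What the generator knows and the analysis must recover."""

    kernels: np.ndarray  # channels x kernel_samples, at the EEG rate
    word_boundaries: List[Tuple[float, float]]
    pause_intervals: List[Tuple[float, float]]
    clean_eeg: np.ndarray  # channels x samples, before noise


@dataclass
class SimRecord:
    subject: int
    condition: str
    segment: int
    envelope: EnvelopeSeries
    word_boundaries: List[Tuple[float, float]]
    eeg: EEGRecording
    truth: GroundTruth


@dataclass
class SyntheticDataset:
    config: SimConfig
    records: List[SimRecord]

    def get(self, subject: int, condition: str) -> List[SimRecord]:
        out = [r for r in self.records
               if r.subject == subject and r.condition == condition]
        return sorted(out, key=lambda r: r.segment)


def _lognormal_params(mean: float, sd: float) -> Tuple[float, float]:
    """(mu, sigma) of a lognormal with the given distribution mean and sd."""
    if sd == 0:
        return np.log(mean), 0.0
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, np.sqrt(sigma2)


def _word_burst(n: int, fs: float, syllable_rate: float, edge_ms: float,
                amplitude: float) -> np.ndarray:
    """One word-shaped envelope burst of ``n`` samples.

    Half-wave-rectified sinusoid at the syllabic rate (one amplitude bump
    per syllable, with a small positivity floor so the burst is strictly
    positive in its interior) under a raised-cosine attack/decay contour.
    First and last samples are small but nonzero, so zero-valued samples
    occur exactly in pauses.  The deep syllabic modulation is what places
    the envelope's modulation peak at the syllabic rate rather than at the
    slower word rate.
    """
    t = np.arange(n) / fs
    syllabic = 0.05 + 0.95 * np.maximum(np.sin(2 * np.pi * syllable_rate * t), 0.0)
    n_edge = max(int(round(edge_ms / 1000.0 * fs)), 1)
    k = np.arange(n)
    ramp = lambda m: 0.5 * (1.0 - np.cos(np.pi * np.minimum(m, n_edge + 1) / (n_edge + 1)))
    window = ramp(k + 1.0) * ramp(float(n) - k)
    return amplitude * syllabic * window


def _word_and_gap_samples(config: SimConfig, subject: int, segment: int
                          ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-word durations, natural gaps (samples) and amplitudes.

    Drawn from the (subject, segment) stream so that the word sequence is
    identical across pause conditions, which is what makes the
    pause-removed stimuli of the three conditions coincide exactly.
    """
    rng = config.rng(subject, segment, 0)
    fs = config.fs_env
    n_words = config.n_words_per_segment
    mu_w, sig_w = _lognormal_params(config.word_duration_mean, config.word_duration_sd)
    mu_p, sig_p = _lognormal_params(config.natural_pause_mean, max(config.natural_pause_sd, 1e-12))
    word_s = rng.lognormal(mu_w, sig_w, size=n_words)
    gap_s = rng.lognormal(mu_p, sig_p, size=n_words - 1)
    amps = rng.lognormal(*_lognormal_params(1.0, 0.25), size=n_words)
    word_n = np.maximum(np.round(word_s * fs).astype(int), int(round(0.06 * fs)))
    gap_n = np.maximum(np.round(gap_s * fs).astype(int), 1)
    return word_n, gap_n, amps


def simulate_envelope(config: SimConfig, condition: str, subject: int = 0,
                      segment: int = 0) -> Tuple[EnvelopeSeries, List[Tuple[float, float]]]:
    """Generate one segment's broadband envelope and its word boundaries.

    The inserted silent pause for ``condition`` is appended to the natural
    gap between each pair of consecutive words (``n_words - 1`` insertions;
    nothing after the final word).  All durations are rounded to whole
    samples at ``config.fs_env`` so that pause excision reproduces an
    identical concatenated signal across conditions.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}, got {condition!r}")
    fs = config.fs_env
    inserted_n = int(round(CONDITION_PAUSE_S[condition] * fs))
    word_n, gap_n, amps = _word_and_gap_samples(config, subject, segment)

    lead = int(round(config.lead_silence_s * fs))
    trail = int(round(config.trail_silence_s * fs))
    total = lead + int(word_n.sum()) + int(gap_n.sum()) + inserted_n * (len(word_n) - 1) + trail
    env = np.zeros(total)
    boundaries: List[Tuple[float, float]] = []
    pos = lead
    for i, n in enumerate(word_n):
        env[pos:pos + n] = _word_burst(int(n), fs, config.syllable_rate_hz,
                                       config.attack_decay_ms, amps[i])
        boundaries.append((pos / fs, (pos + int(n)) / fs))
        pos += int(n)
        if i < len(word_n) - 1:
            pos += int(gap_n[i]) + inserted_n
    series = EnvelopeSeries(values=env, fs=fs, band="broadband")
    return series, boundaries


def pause_intervals_from_boundaries(boundaries: Sequence[Tuple[float, float]],
                                    duration_s: float) -> List[Tuple[float, float]]:
    """The complement of the word intervals: leading, inter-word and trailing
    silence.  Together with the words these tile [0, duration]."""
    out: List[Tuple[float, float]] = []
    prev = 0.0
    for on, off in boundaries:
        if on > prev + 1e-12:
            out.append((prev, on))
        prev = off
    if duration_s > prev + 1e-12:
        out.append((prev, duration_s))
    return out


def _make_kernels(config: SimConfig, subject: int, fs: float) -> np.ndarray:
    """Per-channel biphasic response kernels at rate ``fs``."""
    spec = config.kernel_spec
    rng = config.rng(subject, 17)
    n = max(int(round(spec.duration_ms / 1000.0 * fs)), 2)
    t = np.arange(n) / fs * 1000.0  # ms
    gains = rng.normal(spec.gain_mean, spec.gain_sd, size=config.n_channels)
    jitter = rng.uniform(-spec.latency_jitter_ms, spec.latency_jitter_ms,
                         size=config.n_channels)
    kernels = np.empty((config.n_channels, n))
    for c in range(config.n_channels):
        lat = spec.latency_ms + jitter[c]
        w = spec.width_ms
        pos = np.exp(-0.5 * ((t - lat) / w) ** 2)
        neg = 0.6 * np.exp(-0.5 * ((t - lat - 1.6 * w) / w) ** 2)
        slow = spec.slow_gain * np.exp(
            -0.5 * ((t - lat - spec.slow_latency_ms) / spec.slow_width_ms) ** 2)
        kernels[c] = gains[c] * (pos - neg + slow)
    return kernels


_NOISE_FIR_CACHE: dict = {}


def _one_over_f_fir(fs: float, exponent: float) -> np.ndarray:
    """Fixed FIR whose amplitude response approximates f^(-exponent/2), with
    no DC.  The filter is designed once per (fs, exponent) over an 8-second
    grid, so the shaped noise is a stationary process whose distribution
    does not depend on the length of the segment it is generated for."""
    key = (float(fs), float(exponent))
    if key not in _NOISE_FIR_CACHE:
        L = int(round(8.0 * fs))
        freqs = np.fft.rfftfreq(L, d=1.0 / fs)
        amp = np.zeros_like(freqs)
        amp[1:] = freqs[1:] ** (-exponent / 2.0)
        h = np.fft.irfft(amp, n=L)
        h = np.roll(h, L // 2) * np.hamming(L)  # linear-phase, windowed
        _NOISE_FIR_CACHE[key] = h
    return _NOISE_FIR_CACHE[key]


def _one_over_f_noise(rng: np.random.Generator, n: int, fs: float,
                      exponent: float) -> np.ndarray:
    """Unit-variance stationary noise with power spectral density
    proportional to 1/f^exponent (white noise shaped by a fixed FIR)."""
    h = _one_over_f_fir(fs, exponent)
    white = rng.standard_normal(n + h.size - 1)
    x = signal.fftconvolve(white, h, mode="valid")
    sd = x.std()
    return x / sd if sd > 0 else x


def onset_drive_from_pauses(env: np.ndarray, fs: float,
                            pause_intervals: Sequence[Tuple[float, float]],
                            window_s: float = ONSET_WINDOW_S,
                            recovery_tau_s: float = 0.0) -> np.ndarray:
    """Envelope restricted to the first ``window_s`` after each pause, zero
    elsewhere.

    With ``recovery_tau_s > 0`` each onset is scaled by
    ``1 - exp(-pause_duration / tau)``: the evoked onset response recovers
    from adaptation during silence, so onsets after longer pauses drive
    larger responses (the release-from-adaptation behaviour of the auditory
    late response).
    """
    drive = np.zeros_like(env)
    n = env.size
    win = int(round(window_s * fs))
    for ps, pe in pause_intervals:
        start = int(round(pe * fs))
        if start >= n:
            continue
        factor = 1.0
        if recovery_tau_s > 0:
            factor = 1.0 - np.exp(-(pe - ps) / recovery_tau_s)
        drive[start:start + win] = factor * env[start:start + win]
    return drive


def simulate_eeg(envelope: EnvelopeSeries, config: SimConfig,
                 word_boundaries: Optional[Sequence[Tuple[float, float]]] = None,
                 subject: int = 0, segment: int = 0, condition: str = "natural",
                 kernels: Optional[np.ndarray] = None,
                 ) -> Tuple[EEGRecording, GroundTruth]:
    """Generate EEG for one segment by the linear evoked-response model.

    channel = onset_gain * (kernel (*) onset_drive)
            + sustained_gain * (kernel (*) envelope) + 1/f noise at ``snr_db``.

    The envelope is resampled to ``config.fs_eeg`` if needed.  Noise is drawn
    from the (subject, segment, condition) stream; the call is deterministic
    given the configuration seed.  An explicit channels x taps ``kernels``
    array overrides the kernel spec (useful for controlled recovery tests).
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    fs = config.fs_eeg
    env = envelope.values
    if envelope.fs != fs:
        frac = _as_ratio(fs, envelope.fs)
        env = signal.resample_poly(env, frac[0], frac[1])
        env = np.clip(env, 0.0, None)
    n = env.size

    if word_boundaries is None:
        pauses = _zero_run_intervals(envelope.values, envelope.fs)
    else:
        pauses = pause_intervals_from_boundaries(word_boundaries, envelope.duration_s)

    if kernels is None:
        kernels = _make_kernels(config, subject, fs)
    else:
        kernels = np.atleast_2d(np.asarray(kernels, dtype=float))
        if kernels.shape[0] != config.n_channels:
            raise ValueError("kernels first axis must equal n_channels")
    clean = _clean_response(env, fs, pauses, kernels, config)

    data = clean.copy()
    if np.isfinite(config.snr_db):
        # the background-noise amplitude is a property of the subject, not
        # of the stimulus: it is calibrated so that the *natural* condition
        # of this (subject, segment) sits at snr_db, and the same absolute
        # level is reused for the pause-inserted conditions
        if config.noise_reference == "natural" and condition != "natural":
            ref_env, ref_bounds = simulate_envelope(config, "natural",
                                                    subject, segment)
            ref_vals = ref_env.values
            if ref_env.fs != fs:
                frac = _as_ratio(fs, ref_env.fs)
                ref_vals = np.clip(signal.resample_poly(ref_vals, *frac), 0.0, None)
            ref_pauses = pause_intervals_from_boundaries(ref_bounds,
                                                         ref_env.duration_s)
            ref_clean = _clean_response(ref_vals, fs, ref_pauses, kernels, config)
        else:
            ref_clean = clean
        ref_rms = np.sqrt(np.mean(ref_clean ** 2, axis=1))
        cond_idx = CONDITIONS.index(condition)
        rng = config.rng(subject, segment, cond_idx, 1)
        for c in range(config.n_channels):
            noise = _one_over_f_noise(rng, n, fs, config.noise_exponent)
            noise_sd = (ref_rms[c] * 10.0 ** (-config.snr_db / 20.0)
                        if ref_rms[c] > 0 else 1.0)
            data[c] = clean[c] + noise_sd * noise

    eeg = EEGRecording(data=data, fs=fs, subject_id=f"S{subject:02d}",
                       segment_id=segment, condition_label=condition)
    truth = GroundTruth(kernels=kernels,
                        word_boundaries=list(word_boundaries or []),
                        pause_intervals=pauses, clean_eeg=clean)
    return eeg, truth


def _clean_response(env: np.ndarray, fs: float, pauses, kernels: np.ndarray,
                    config: SimConfig) -> np.ndarray:
    """Noise-free EEG: onset and sustained drives convolved with the
    per-channel kernels."""
    n = env.size
    drive = onset_drive_from_pauses(env, fs, pauses,
                                    recovery_tau_s=config.onset_recovery_tau_s)
    clean = np.empty((kernels.shape[0], n))
    for c in range(kernels.shape[0]):
        resp = np.zeros(n)
        if config.onset_gain:
            resp += config.onset_gain * signal.fftconvolve(drive, kernels[c])[:n]
        if config.sustained_gain:
            resp += config.sustained_gain * signal.fftconvolve(env, kernels[c])[:n]
        clean[c] = resp
    return clean


def _zero_run_intervals(env: np.ndarray, fs: float,
                        min_s: float = 0.02) -> List[Tuple[float, float]]:
    """Intervals where the envelope is exactly zero for at least ``min_s``."""
    zero = env == 0.0
    edges = np.diff(zero.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if zero.size and zero[0]:
        starts.insert(0, 0)
    if zero.size and zero[-1]:
        ends.append(zero.size)
    out = []
    for s, e in zip(starts, ends):
        if (e - s) / fs >= min_s:
            out.append((s / fs, e / fs))
    return out


def _as_ratio(fs_out: float, fs_in: float) -> Tuple[int, int]:
    from fractions import Fraction
    frac = Fraction(fs_out / fs_in).limit_denominator(10000)
    return frac.numerator, frac.denominator


def simulate_segment(config: SimConfig, condition: str, subject: int,
                     segment: int) -> SimRecord:
    env, bounds = simulate_envelope(config, condition, subject, segment)
    eeg, truth = simulate_eeg(env, config, bounds, subject, segment, condition)
    return SimRecord(subject=subject, condition=condition, segment=segment,
                     envelope=env, word_boundaries=bounds, eeg=eeg, truth=truth)


def simulate_dataset(config: SimConfig,
                     conditions: Sequence[str] = CONDITIONS,
                     subjects: Optional[Sequence[int]] = None) -> SyntheticDataset:
    """Generate the full cohort (or a subset of subjects/conditions)."""
    if subjects is None:
        subjects = range(config.n_subjects)
    records = [simulate_segment(config, cond, subj, seg)
               for subj in subjects
               for cond in conditions
               for seg in range(config.n_segments_per_condition)]
    return SyntheticDataset(config=config, records=records)


def write_fixture(dataset: SyntheticDataset, directory) -> Dict:
    """Write a dataset to disk (WAV envelope, TSV boundaries, HDF5 EEG) with a
    JSON manifest carrying the configuration and seed.  Round-trips through
    :func:`read_fixture`."""
    if not dataset.records:
        raise ValueError("refusing to write an empty dataset")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for rec in dataset.records:
        stem = f"sub-{rec.subject:02d}_cond-{rec.condition}_seg-{rec.segment}"
        wav = directory / f"{stem}.wav"
        tsv = directory / f"{stem}_words.tsv"
        h5 = directory / f"{stem}_eeg.h5"
        ptio.write_wav(wav, rec.envelope.values, rec.envelope.fs)
        ptio.write_word_boundaries(tsv, rec.word_boundaries)
        ptio.write_eeg_h5(h5, rec.eeg)
        entries.append({"subject": rec.subject, "condition": rec.condition,
                        "segment": rec.segment, "wav": wav.name,
                        "words": tsv.name, "eeg": h5.name})
    cfg = asdict(dataset.config)
    manifest = {"seed": dataset.config.seed, "config": cfg, "records": entries}
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def read_fixture(directory) -> SyntheticDataset:
    """Read a fixture directory written by :func:`write_fixture`.

    Ground-truth kernels and clean EEG are not stored on disk; records come
    back with ``truth=None``-equivalent empty ground truth (boundaries only).
    """
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    cfg_dict = dict(manifest["config"])
    cfg_dict["kernel_spec"] = KernelSpec(**cfg_dict["kernel_spec"])
    config = SimConfig(**cfg_dict)
    records = []
    for e in manifest["records"]:
        env_vals, fs = ptio.read_wav(directory / e["wav"])
        env = EnvelopeSeries(values=env_vals, fs=fs, band="broadband")
        bounds = ptio.read_word_boundaries(directory / e["words"])
        eeg = ptio.read_eeg_h5(directory / e["eeg"])
        truth = GroundTruth(kernels=np.empty((0, 0)), word_boundaries=bounds,
                            pause_intervals=pause_intervals_from_boundaries(
                                bounds, env.duration_s),
                            clean_eeg=np.empty((0, 0)))
        records.append(SimRecord(subject=e["subject"], condition=e["condition"],
                                 segment=e["segment"], envelope=env,
                                 word_boundaries=bounds, eeg=eeg, truth=truth))
    return SyntheticDataset(config=config, records=records)
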