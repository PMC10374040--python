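"""Pause insertion, Hilbert envelope and band-limiting contracts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal

from pausetrack import (AnnotatedAudio, EnvelopeSeries, bandlimit_envelope,
                        extract_envelope, insert_pauses, modulation_spectrum)


def _toy_audio(fs=1000.0):
    n = int(0.9 * fs)
    rng = np.random.default_rng(0)
    samples = rng.standard_normal(n) * 0.1
    return AnnotatedAudio(samples=samples, fs=fs,
                          word_boundaries=[(0.0, 0.4), (0.5, 0.9)])


class TestInsertPauses:
    def test_zero_pause_is_identity(self):
        audio = _toy_audio()
        out = insert_pauses(audio, 0.0)
        assert np.array_equal(out.samples, audio.samples)
        assert out.word_boundaries == audio.word_boundaries

    def test_two_word_splice_arithmetic(self):
        audio = _toy_audio()
        out = insert_pauses(audio, 0.25)
        assert out.duration_s == pytest.approx(1.15)
        assert out.word_boundaries[0] == pytest.approx((0.0, 0.4))
        assert out.word_boundaries[1] == pytest.approx((0.75, 1.15))
        # inserted region is exact digital silence
        fs = audio.fs
        assert np.all(out.samples[int(0.4 * fs):int(0.65 * fs)] == 0)

    def test_length_exact_invariant(self):
        fs = 500.0
        rng = np.random.default_rng(1)
        bounds = [(0.1 * i, 0.1 * i + 0.08) for i in range(8)]
        audio = AnnotatedAudio(samples=rng.standard_normal(int(fs)), fs=fs,
                               word_boundaries=bounds)
        for pause_s in (0.1, 0.25, 0.5):
            out = insert_pauses(audio, pause_s)
            expect = audio.samples.size + 7 * int(round(pause_s * fs))
            assert out.samples.size == expect

    def test_short_vs_long_difference(self):
        audio = _toy_audio()
        short = insert_pauses(audio, 0.25)
        long_ = insert_pauses(audio, 0.5)
        assert long_.duration_s - short.duration_s == pytest.approx(0.25)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(pause_ms=st.integers(0, 600), n_words=st.integers(2, 6),
           seed=st.integers(0, 7))
    def test_length_exact_for_any_pause_and_word_count(self, pause_ms,
                                                       n_words, seed):
        fs = 250.0
        rng = np.random.default_rng(seed)
        bounds = [(0.1 * i, 0.1 * i + 0.08) for i in range(n_words)]
        n = int(round(0.1 * n_words * fs))
        audio = AnnotatedAudio(samples=rng.standard_normal(n) * 0.1, fs=fs,
                               word_boundaries=bounds)
        out = insert_pauses(audio, pause_ms / 1000.0)
        gap = int(round(pause_ms / 1000.0 * fs))
        assert out.samples.size == n + (n_words - 1) * gap
        # all word contents preserved sample-exactly
        for (on, off), (on2, off2) in zip(bounds, out.word_boundaries):
            a = audio.samples[int(round(on * fs)):int(round(off * fs))]
            b = out.samples[int(round(on2 * fs)):int(round(off2 * fs))]
            assert np.array_equal(a, b)

    def test_requires_boundaries(self):
        audio = AnnotatedAudio(samples=np.zeros(100), fs=100.0)
        with pytest.raises(ValueError):
            insert_pauses(audio, 0.25)


class TestExtractEnvelope:
    def test_pure_tone_gives_constant_amplitude(self):
        fs = 8000.0
        t = np.arange(int(2 * fs)) / fs
        audio = AnnotatedAudio(samples=0.7 * np.sin(2 * np.pi * 440 * t), fs=fs)
        env = extract_envelope(audio)
        interior = env.values[int(0.1 * fs):-int(0.1 * fs)]
        assert np.allclose(interior, 0.7, rtol=0.01)

    def test_silence_gives_zero(self):
        audio = AnnotatedAudio(samples=np.zeros(1000), fs=1000.0)
        assert np.all(extract_envelope(audio).values == 0)

    def test_am_tone_recovers_modulator(self):
        fs = 8000.0
        t = np.arange(int(4 * fs)) / fs
        modulator = 1 + 0.5 * np.sin(2 * np.pi * 3 * t)
        audio = AnnotatedAudio(samples=modulator * np.sin(2 * np.pi * 1000 * t),
                               fs=fs)
        env = extract_envelope(audio)
        sl = slice(int(0.2 * fs), -int(0.2 * fs))
        rms_err = np.sqrt(np.mean((env.values[sl] - modulator[sl]) ** 2))
        assert rms_err / np.sqrt(np.mean(modulator[sl] ** 2)) < 0.02

    def test_sign_invariance(self):
        audio = _toy_audio()
        flipped = AnnotatedAudio(samples=-audio.samples, fs=audio.fs)
        assert np.allclose(extract_envelope(audio).values,
                           extract_envelope(flipped).values)

    def test_empty_waveform_rejected(self):
        with pytest.raises(ValueError):
            extract_envelope(AnnotatedAudio(samples=np.array([]), fs=100.0))


class TestBandlimit:
    fs = 512.0

    def _env(self, f):
        t = np.arange(int(60 * self.fs)) / self.fs
        return EnvelopeSeries(values=1.0 + 0.5 * np.sin(2 * np.pi * f * t),
                              fs=self.fs, band="broadband")

    def test_passband_amplitude_preserved(self):
        out = bandlimit_envelope(self._env(2.0), "delta", fs_out=128.0)
        interior = out.values[int(10 * 128):-int(10 * 128)]
        amp = np.sqrt(2) * interior.std()
        assert amp == pytest.approx(0.5, rel=0.05)

    def test_stopband_attenuation(self):
        out = bandlimit_envelope(self._env(6.0), "delta", fs_out=128.0)
        interior = out.values[int(10 * 128):-int(10 * 128)]
        amp = np.sqrt(2) * interior.std()
        assert 20 * np.log10(0.5 / max(amp, 1e-12)) >= 20.0

    def test_zero_phase_no_group_delay(self):
        out = bandlimit_envelope(self._env(2.0), "delta", fs_out=self.fs)
        t = np.arange(int(60 * self.fs)) / self.fs
        ref = 0.5 * np.sin(2 * np.pi * 2.0 * t)
        sl = slice(int(10 * self.fs), int(50 * self.fs))
        xc = signal.correlate(out.values[sl], ref[sl], mode="full")
        lag = np.argmax(xc) - (len(ref[sl]) - 1)
        assert lag == 0

    def test_rejects_band_limited_input(self):
        env = bandlimit_envelope(self._env(2.0), "delta")
        with pytest.raises(ValueError):
            bandlimit_envelope(env, "theta")


class TestModulationSpectrum:
    def test_unit_normalization(self):
        fs = 128.0
        t = np.arange(int(30 * fs)) / fs
        env = EnvelopeSeries(values=1 + 0.5 * np.sin(2 * np.pi * 4.5 * t), fs=fs)
        freqs, power = modulation_spectrum(env)
        df = freqs[1] - freqs[0]
        assert power.sum() * df == pytest.approx(1.0)

    def test_sinusoid_peak_at_nearest_grid_frequency(self):
        fs = 128.0
        t = np.arange(int(30 * fs)) / fs
        env = EnvelopeSeries(values=1 + 0.5 * np.sin(2 * np.pi * 4.5 * t), fs=fs)
        freqs, power = modulation_spectrum(env)
        assert abs(freqs[np.argmax(power)] - 4.5) <= (freqs[1] - freqs[0])

    def test_too_short_rejected(self):
        env = EnvelopeSeries(values=np.ones(10), fs=128.0)
        with pytest.raises(ValueError):
            modulation_spectrum(env)

    def test_inserted_pauses_create_delta_peak(self):
        from pausetrack import SimConfig, simulate_envelope
        cfg = SimConfig(n_channels=1, fs_eeg=128.0, fs_env=128.0,
                        n_words_per_segment=150, seed=5)
        spectra = {}
        for cond in ("natural", "short"):
            env, _ = simulate_envelope(cfg, cond)
            freqs, power = spectra[cond] = modulation_spectrum(env)
        f = spectra["natural"][0]
        delta = (f >= 1) & (f <= 4)
        theta = (f > 4) & (f <= 8)
        ratio_nat = spectra["natural"][1][delta].sum() / spectra["natural"][1][theta].sum()
        ratio_short = spectra["short"][1][delta].sum() / spectra["short"][1][theta].sum()
        assert ratio_short > ratio_nat
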