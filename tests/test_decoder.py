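"""The regularized lagged-regression decoder against independent oracles."""

import numpy as np
import pytest

from pausetrack import (EEGRecording, EnvelopeSeries, EnvelopeDecoder, LagSpec,
                        build_lagged_design, build_regularizer, fit_decoder,
                        load_decoder, reconstruct, save_decoder, score)
from pausetrack.decoder import UndefinedScoreError

FS = 128.0


def _spec(n_lags, fs=FS):
    return LagSpec(0.0, (n_lags - 1) / fs * 1000.0, fs)


def _oracle_fit(R, S, lam, M):
    """Brute-force normal equations by explicit dense inversion, with the
    same row-deletion + centering convention as the implementation."""
    cm = R.mean(axis=0)
    sm = S.mean()
    Rc = R - cm
    Sc = S - sm
    return np.linalg.inv(Rc.T @ Rc + lam * M) @ (Rc.T @ Sc)


class TestLaggedDesign:
    def test_single_lag_is_the_channel(self):
        eeg = EEGRecording(data=np.array([[1.0, 2.0, 3.0]]), fs=FS)
        R = build_lagged_design(eeg, _spec(1))
        assert np.array_equal(R, [[1.0], [2.0], [3.0]])

    def test_two_lags_zero_padded(self):
        eeg = EEGRecording(data=np.array([[1.0, 2.0, 3.0]]), fs=FS)
        R = build_lagged_design(eeg, _spec(2))
        assert np.array_equal(R, [[1.0, 2.0], [2.0, 3.0], [3.0, 0.0]])

    def test_two_channels_single_lag(self):
        data = np.array([[1.0, 2.0], [5.0, 6.0]])
        R = build_lagged_design(EEGRecording(data=data, fs=FS), _spec(1))
        assert np.array_equal(R, data.T)

    def test_lag_window_longer_than_recording(self):
        eeg = EEGRecording(data=np.ones((1, 3)), fs=FS)
        with pytest.raises(ValueError):
            build_lagged_design(eeg, _spec(5))


class TestRegularizer:
    def test_printed_three_lag_pattern(self):
        M = build_regularizer(_spec(3), 1).matrix
        assert np.array_equal(M, [[1, -1, 0], [-1, 2, -1], [0, -1, 1]])

    def test_annihilates_constants_per_block(self):
        M = build_regularizer(_spec(4), 3).matrix
        const = np.tile(np.ones(4), 3)
        assert np.allclose(M @ const, 0)

    def test_positive_semidefinite(self):
        M = build_regularizer(_spec(6), 2).matrix
        evals = np.linalg.eigvalsh(M)
        assert evals.min() > -1e-12

    def test_block_diagonal_no_cross_channel_coupling(self):
        M = build_regularizer(_spec(3), 2).matrix
        assert np.all(M[:3, 3:] == 0) and np.all(M[3:, :3] == 0)

    def test_single_lag_identity_block(self):
        M = build_regularizer(_spec(1), 4).matrix
        assert np.array_equal(M, np.eye(4))


class TestFit:
    def test_identity_regression(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(200)
        eeg = EEGRecording(data=np.stack([x, rng.standard_normal(200)]), fs=FS)
        spec = _spec(1)
        R = build_lagged_design(eeg, spec)
        M = build_regularizer(spec, 2)
        m = fit_decoder(R, x, 0.0, M, lag_spec=spec)
        assert np.allclose(m.flat_weights, [1.0, 0.0], atol=1e-10)
        assert np.allclose(reconstruct(m, R), x, atol=1e-10)

    @pytest.mark.parametrize("lam", [0.01, 1.0, 1e6])
    def test_matches_dense_inversion_oracle(self, lam):
        rng = np.random.default_rng(int(lam * 100) % 2**31)
        spec = _spec(3)
        M = build_regularizer(spec, 2)
        R = rng.standard_normal((200, 6))
        S = rng.standard_normal(200)
        m = fit_decoder(R, S, lam, M, lag_spec=spec)
        g_oracle = _oracle_fit(R, S, lam, M.matrix)
        assert np.max(np.abs(m.flat_weights - g_oracle)) < 1e-8

    def test_mask_equals_physical_row_deletion(self):
        rng = np.random.default_rng(1)
        spec = _spec(4)
        M = build_regularizer(spec, 1)
        R = rng.standard_normal((300, 4))
        S = rng.standard_normal(300)
        valid = rng.random(300) > 0.3
        m_masked = fit_decoder(R, S, 2.5, M, valid=valid, lag_spec=spec)
        m_deleted = fit_decoder(R[valid], S[valid], 2.5, M, lag_spec=spec)
        assert np.max(np.abs(m_masked.flat_weights
                             - m_deleted.flat_weights)) < 1e-12

    def test_scale_property(self):
        rng = np.random.default_rng(2)
        spec = _spec(3)
        M = build_regularizer(spec, 2)
        R = rng.standard_normal((250, 6))
        S = rng.standard_normal(250)
        m1 = fit_decoder(R, S, 1.0, M, lag_spec=spec)
        m2 = fit_decoder(R, 3.0 * S, 1.0, M, lag_spec=spec)
        assert np.allclose(m2.flat_weights, 3.0 * m1.flat_weights, atol=1e-10)
        r1, _ = score(reconstruct(m1, R), S)
        r2, _ = score(reconstruct(m2, R), 3.0 * S)
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_penalty_monotone_in_lambda(self):
        rng = np.random.default_rng(3)
        spec = _spec(5)
        M = build_regularizer(spec, 2)
        R = rng.standard_normal((400, 10))
        S = R @ rng.standard_normal(10) + 0.1 * rng.standard_normal(400)
        prev = np.inf
        for lam in [0.01, 1.0, 100.0, 1e4, 1e8, 1e12]:
            m = fit_decoder(R, S, lam, M, lag_spec=spec)
            g = m.flat_weights
            rough = g @ M.matrix @ g
            assert rough <= prev + 1e-12
            prev = rough
        # in the limit the solution lies in the penalty's null space
        assert prev < 1e-12

    def test_extreme_lambda_with_identity_block_shrinks_to_zero(self):
        rng = np.random.default_rng(4)
        spec = _spec(1)
        M = build_regularizer(spec, 3)
        R = rng.standard_normal((200, 3))
        S = rng.standard_normal(200)
        m = fit_decoder(R, S, 1e12, M, lag_spec=spec)
        assert np.linalg.norm(m.flat_weights) < 1e-6

    def test_singular_unregularized_system_advises_lambda(self):
        x = np.random.default_rng(5).standard_normal(100)
        R = np.stack([x, x], axis=1)  # collinear columns
        M = build_regularizer(_spec(1), 2)
        with pytest.raises(np.linalg.LinAlgError, match="lambda"):
            fit_decoder(R, x, 0.0, M)

    def test_negative_lambda_rejected(self):
        M = build_regularizer(_spec(1), 1)
        with pytest.raises(ValueError):
            fit_decoder(np.ones((10, 1)), np.ones(10), -1.0, M)


class TestReconstructScore:
    def test_zero_weights_zero_reconstruction_and_linearity(self):
        rng = np.random.default_rng(6)
        spec = _spec(3)
        M = build_regularizer(spec, 1)
        R = rng.standard_normal((100, 3))
        S = rng.standard_normal(100)
        m1 = fit_decoder(R, S, 1.0, M, lag_spec=spec)
        m0 = fit_decoder(R, np.zeros(100), 1.0, M, lag_spec=spec)
        assert np.allclose(reconstruct(m0, R), 0.0)
        import dataclasses
        m_sum = dataclasses.replace(m1, weights=m1.weights + m1.weights)
        assert np.allclose(reconstruct(m_sum, R),
                           2 * reconstruct(m1, R), atol=1e-12)

    def test_perfect_and_anticorrelated(self):
        s = np.array([0.3, -1.2, 0.8, 2.0])
        r, mse = score(s, s)
        assert r == pytest.approx(1.0) and mse == 0.0
        r, _ = score(-s, s)
        assert r == pytest.approx(-1.0)

    def test_hand_arithmetic(self):
        S = np.array([1.0, 2.0, 3.0, 4.0])
        S_hat = np.array([2.0, 4.0, 6.0, 8.0])
        r, mse = score(S_hat, S)
        assert r == pytest.approx(1.0)
        assert mse == pytest.approx(7.5)

    def test_degenerate_scores_flagged(self):
        with pytest.raises(UndefinedScoreError):
            score(np.ones(2), np.ones(2))
        with pytest.raises(UndefinedScoreError):
            score(np.ones(10), np.arange(10.0))

    def test_masked_scoring_uses_valid_samples_only(self):
        S = np.array([1.0, 2.0, 3.0, 4.0, 100.0])
        S_hat = np.array([1.0, 2.0, 3.0, 4.0, -50.0])
        valid = np.array([True, True, True, True, False])
        r, mse = score(S_hat, S, valid=valid)
        assert r == pytest.approx(1.0) and mse == 0.0


class TestModelObject:
    def test_fit_summary_and_heldout_evaluation(self, delta_segments):
        train, test = delta_segments[0], delta_segments[1]
        model = EnvelopeDecoder(train.envelope, train.eeg,
                                LagSpec(0, 300, FS))
        res = model.fit(lam=100.0)
        assert res.params.shape == (LagSpec(0, 300, FS).n_lags,
                                    train.eeg.n_channels)
        text = res.summary()
        assert "lambda" in text and "delta" in text
        r, mse = res.evaluate(test.envelope, test.eeg)
        assert -1 <= r <= 1 and mse >= 0
        assert np.isfinite(res.train_r)

    def test_round_trip_serialization(self, tmp_path, delta_segments):
        seg = delta_segments[0]
        res = EnvelopeDecoder(seg.envelope, seg.eeg, LagSpec(0, 300, FS)).fit(10.0)
        path = tmp_path / "decoder.h5"
        save_decoder(path, res.fitted)
        back = load_decoder(path)
        assert np.array_equal(back.weights, res.fitted.weights)
        assert back.lam == res.fitted.lam
        assert back.lag_spec == res.fitted.lag_spec
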