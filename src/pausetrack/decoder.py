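"""Backward mTRF (stimulus-reconstruction) decoder.

The decoder is a multichannel lagged linear map g(tau, n) reconstructing the
band-limited speech envelope S(t) from the EEG r:

    S_hat(t) = sum_n sum_tau r(t + tau, n) g(tau, n)

with the anticausal convention (EEG *after* t predicts the stimulus at t).
Weights are estimated by Tikhonov-regularized least squares,

    g = (R'R + lambda M)^{-1} R'S

where R is the lagged design and M a second-difference smoothness penalty
over lags (tridiagonal blocks with diagonal [1, 2, ..., 2, 1] and
off-diagonals -1), applied block-diagonally per channel with no
cross-channel coupling.  Samples excluded by the feature mask (NaN-style
exclusion) are dropped from the least-squares fit and from scoring.

A statsmodels-style surface is provided: :class:`EnvelopeDecoder` is the
model object built from data; its :meth:`~EnvelopeDecoder.fit` returns a
:class:`DecoderResults` carrying the weights, fit diagnostics and a
``summary()`` table.  The plain functions (:func:`build_lagged_design`,
:func:`fit_decoder`, :func:`reconstruct`, :func:`score`) are the primitive
layer the evaluation code uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import linalg as sla

from .datatypes import EEGRecording, EnvelopeSeries

__all__ = [
    "LagSpec", "RegularizerM", "DecoderModel", "UndefinedScoreError",
    "build_lagged_design", "build_regularizer", "fit_decoder",
    "reconstruct", "score", "save_decoder", "load_decoder",
    "EnvelopeDecoder", "DecoderResults",
]


class UndefinedScoreError(ValueError):
    """Raised when a correlation/MSE score is undefined (too few valid
    samples, or zero variance in one of the series)."""


@dataclass(frozen=True)
class LagSpec:
    """Lag window of the decoder, in milliseconds at a given rate.

    The default window is 0-300 ms; a 0-500 ms variant is used for the
    pauses-removed analysis.  ``n_lags = round((max-min)/1000*fs) + 1``.
    """

    lag_min_ms: float = 0.0
    lag_max_ms: float = 300.0
    fs: float = 128.0

    def __post_init__(self) -> None:
        if self.lag_min_ms > self.lag_max_ms:
            raise ValueError("lag_min_ms must not exceed lag_max_ms")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def lag_min_samples(self) -> int:
        return int(round(self.lag_min_ms / 1000.0 * self.fs))

    @property
    def n_lags(self) -> int:
        return int(round((self.lag_max_ms - self.lag_min_ms) / 1000.0 * self.fs)) + 1

    @property
    def lags_samples(self) -> np.ndarray:
        return self.lag_min_samples + np.arange(self.n_lags)


@dataclass
class RegularizerM:
    """Block-diagonal second-difference penalty; one tridiagonal block per
    channel.  Symmetric, positive semidefinite, annihilates the per-channel
    constant vector."""

    matrix: np.ndarray
    n_lags: int
    n_channels: int


@dataclass
class DecoderModel:
    """A fitted decoder: weights g(tau, n) plus provenance."""

    weights: np.ndarray  # (n_lags, n_channels)
    lag_spec: LagSpec
    lam: float
    band: str = "broadband"
    trained_on: str = "full"
    condition_label: str = "other"
    col_means: Optional[np.ndarray] = None  # design-column means used in centering
    target_mean: float = 0.0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (self.lag_spec.n_lags,) and self.weights.ndim == 1:
            raise ValueError("1-D weights must have n_lags entries")
        if self.weights.ndim == 1:
            self.weights = self.weights[:, None]
        if self.weights.shape[0] != self.lag_spec.n_lags:
            raise ValueError("weights first axis must be n_lags")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("non-finite decoder weights")

    @property
    def flat_weights(self) -> np.ndarray:
        """Channel-major flattening matching the design's column order."""
        return self.weights.T.ravel()


def build_lagged_design(eeg: EEGRecording, lag_spec: LagSpec) -> np.ndarray:
    """Time x (channels * lags) design matrix.

    Row t holds r(t + tau, n) for every lag tau and channel n; indices past
    the end of the recording are zero-padded.  Columns are channel-major:
    column ``c * n_lags + j`` is channel c at the j-th lag, matching the
    per-channel blocks of the regularizer.
    """
    n = eeg.n_samples
    lags = lag_spec.lags_samples
    if lags[-1] >= n:
        raise ValueError("lag window longer than the recording")
    n_ch = eeg.n_channels
    n_lags = lags.size
    padded = np.concatenate([eeg.data, np.zeros((n_ch, int(lags[-1]) + 1))], axis=1)
    R = np.empty((n, n_ch * n_lags))
    t = np.arange(n)
    for c in range(n_ch):
        for j, lag in enumerate(lags):
            R[:, c * n_lags + j] = padded[c, t + lag]
    return R


def build_regularizer(lag_spec: LagSpec, n_channels: int) -> RegularizerM:
    """Second-difference penalty, block-diagonal over channels.

    Each block is tridiagonal with diagonal [1, 2, ..., 2, 1] and -1 off the
    diagonal; the degenerate single-lag case uses an identity block."""
    n_lags = lag_spec.n_lags
    if n_lags == 1:
        block = np.eye(1)
    else:
        block = (2.0 * np.eye(n_lags)
                 - np.eye(n_lags, k=1) - np.eye(n_lags, k=-1))
        block[0, 0] = 1.0
        block[-1, -1] = 1.0
    M = np.kron(np.eye(n_channels), block)
    return RegularizerM(matrix=M, n_lags=n_lags, n_channels=n_channels)


def fit_decoder(R: np.ndarray, S, lam: float, M: RegularizerM,
                valid: Optional[np.ndarray] = None,
                lag_spec: Optional[LagSpec] = None,
                band: str = "broadband", trained_on: str = "full",
                condition_label: str = "other") -> DecoderModel:
    """Solve the regularized normal equations on the retained samples.

    ``S`` may be an :class:`EnvelopeSeries` (its validity mask is honoured)
    or a plain vector; an explicit ``valid`` mask overrides.  Rows of R and
    the target at excluded samples are dropped; the retained design columns
    and target are mean-centered before solving (the penalty's per-block
    null space contains the constant vector, so no intercept column is
    added).  The solve is a symmetric positive-definite factorization with a
    least-squares fallback; an exactly singular unregularized system raises
    with advice to use lambda > 0.
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    if isinstance(S, EnvelopeSeries):
        target = S.values
        if valid is None:
            valid = S.valid_mask()
        band = S.band if band == "broadband" else band
    else:
        target = np.asarray(S, dtype=float)
    if target.size != R.shape[0]:
        raise ValueError("design rows and target samples misaligned")
    if valid is None:
        valid = np.ones(target.size, dtype=bool)
    Rv = R[valid]
    Sv = target[valid]
    if Rv.shape[0] < Rv.shape[1] and lam == 0:
        raise np.linalg.LinAlgError(
            "underdetermined system at lambda=0; use lambda > 0")

    col_means = Rv.mean(axis=0)
    s_mean = float(Sv.mean())
    Rc = Rv - col_means
    Sc = Sv - s_mean
    if lam == 0 and np.linalg.matrix_rank(Rc) < Rc.shape[1]:
        raise np.linalg.LinAlgError(
            "rank-deficient design at lambda=0 (collinear columns); "
            "use lambda > 0")
    A = Rc.T @ Rc + lam * M.matrix
    b = Rc.T @ Sc
    try:
        c, low = sla.cho_factor(A)
        g = sla.cho_solve((c, low), b)
    except np.linalg.LinAlgError:
        if lam == 0:
            raise np.linalg.LinAlgError(
                "singular normal equations at lambda=0 (collinear design "
                "columns); use lambda > 0")
        g, *_ = np.linalg.lstsq(A, b, rcond=None)
    if lag_spec is None:
        lag_spec = LagSpec(0.0, (M.n_lags - 1) / 128.0 * 1000.0, 128.0)
    weights = g.reshape(M.n_channels, M.n_lags).T
    return DecoderModel(weights=weights, lag_spec=lag_spec, lam=lam, band=band,
                        trained_on=trained_on, condition_label=condition_label,
                        col_means=col_means, target_mean=s_mean)


def reconstruct(model: DecoderModel, R: np.ndarray) -> np.ndarray:
    """S_hat = R g over the design's full time axis."""
    g = model.flat_weights
    if R.shape[1] != g.size:
        raise ValueError("design width does not match decoder weights")
    return R @ g


def score(s_hat: np.ndarray, S, valid: Optional[np.ndarray] = None
          ) -> Tuple[float, float]:
    """Pearson r and MSE between reconstruction and target over valid
    samples only.  Raises :class:`UndefinedScoreError` on degenerate input
    rather than silently returning 0."""
    if isinstance(S, EnvelopeSeries):
        target = S.values
        if valid is None:
            valid = S.valid_mask()
    else:
        target = np.asarray(S, dtype=float)
    s_hat = np.asarray(s_hat, dtype=float)
    if s_hat.size != target.size:
        raise ValueError("series lengths differ")
    if valid is not None:
        s_hat = s_hat[valid]
        target = target[valid]
    if s_hat.size < 3:
        raise UndefinedScoreError("fewer than 3 valid samples")
    if s_hat.std() == 0 or target.std() == 0:
        raise UndefinedScoreError("zero variance in one of the series")
    r = float(np.corrcoef(s_hat, target)[0, 1])
    mse = float(np.mean((s_hat - target) ** 2))
    return r, mse


def save_decoder(path, model: DecoderModel) -> None:
    """Serialize a fitted decoder (weights + metadata) to HDF5."""
    import h5py

    with h5py.File(path, "w") as fh:
        d = fh.create_dataset("weights", data=model.weights)
        d.attrs["lag_min_ms"] = model.lag_spec.lag_min_ms
        d.attrs["lag_max_ms"] = model.lag_spec.lag_max_ms
        d.attrs["fs"] = model.lag_spec.fs
        d.attrs["lambda"] = model.lam
        d.attrs["band"] = model.band
        d.attrs["trained_on"] = model.trained_on
        d.attrs["condition_label"] = model.condition_label


def load_decoder(path) -> DecoderModel:
    import h5py

    with h5py.File(path, "r") as fh:
        d = fh["weights"]
        spec = LagSpec(float(d.attrs["lag_min_ms"]), float(d.attrs["lag_max_ms"]),
                       float(d.attrs["fs"]))
        return DecoderModel(weights=d[()], lag_spec=spec,
                            lam=float(d.attrs["lambda"]),
                            band=str(d.attrs["band"]),
                            trained_on=str(d.attrs["trained_on"]),
                            condition_label=str(d.attrs["condition_label"]))


class EnvelopeDecoder:
    """Backward-mTRF model object: EEG design + envelope target.

    Parameters
    ----------
    envelope : EnvelopeSeries
        Band-limited target, optionally carrying a feature mask.
    eeg : EEGRecording
        Preprocessed (referenced, band-passed, resampled, normalized) EEG at
        the same rate and length.
    lag_spec : LagSpec, optional
        Decoder lag window; defaults to 0-300 ms at the envelope's rate.

    Examples
    --------
    >>> model = EnvelopeDecoder(envelope, eeg)
    >>> res = model.fit(lam=100.0)
    >>> r, mse = res.evaluate(envelope_test, eeg_test)
    """

    def __init__(self, envelope: EnvelopeSeries, eeg: EEGRecording,
                 lag_spec: Optional[LagSpec] = None):
        if envelope.n_samples != eeg.n_samples:
            raise ValueError("envelope and EEG lengths differ")
        if envelope.fs != eeg.fs:
            raise ValueError("envelope and EEG rates differ")
        self.envelope = envelope
        self.eeg = eeg
        self.lag_spec = lag_spec or LagSpec(fs=eeg.fs)
        self.design = build_lagged_design(eeg, self.lag_spec)
        self.regularizer = build_regularizer(self.lag_spec, eeg.n_channels)

    def fit(self, lam: float) -> "DecoderResults":
        model = fit_decoder(self.design, self.envelope, lam, self.regularizer,
                            lag_spec=self.lag_spec, band=self.envelope.band,
                            trained_on=self.envelope.provenance,
                            condition_label=self.eeg.condition_label)
        return DecoderResults(self, model)


class DecoderResults:
    """Results of one decoder fit: weights, training-set diagnostics, and
    out-of-sample evaluation helpers."""

    def __init__(self, model: EnvelopeDecoder, fitted: DecoderModel):
        self.model = model
        self.fitted = fitted
        self.params = fitted.weights
        s_hat = reconstruct(fitted, model.design)
        try:
            self.train_r, self.train_mse = score(s_hat, model.envelope)
        except UndefinedScoreError:
            self.train_r = self.train_mse = float("nan")

    @property
    def lam(self) -> float:
        return self.fitted.lam

    def reconstruct(self, eeg: Optional[EEGRecording] = None) -> np.ndarray:
        design = (self.model.design if eeg is None
                  else build_lagged_design(eeg, self.model.lag_spec))
        return reconstruct(self.fitted, design)

    def evaluate(self, envelope: EnvelopeSeries, eeg: EEGRecording
                 ) -> Tuple[float, float]:
        """Pearson r and MSE of the reconstruction on held-out data."""
        return score(self.reconstruct(eeg), envelope)

    def roughness(self) -> float:
        """The penalty value g' M g (smoothness of the lag profile)."""
        g = self.fitted.flat_weights
        return float(g @ self.model.regularizer.matrix @ g)

    def summary(self) -> str:
        spec = self.model.lag_spec
        lines = [
            "Backward mTRF decoder",
            "=" * 46,
            f"band:             {self.model.envelope.band}",
            f"trained on:       {self.fitted.trained_on}",
            f"condition:        {self.fitted.condition_label}",
            f"channels:         {self.model.eeg.n_channels}",
            f"lag window:       {spec.lag_min_ms:.0f}-{spec.lag_max_ms:.0f} ms "
            f"({spec.n_lags} lags @ {spec.fs:g} Hz)",
            f"lambda:           {self.lam:.4g}",
            f"training r:       {self.train_r:.4f}",
            f"training MSE:     {self.train_mse:.4f}",
            f"roughness g'Mg:   {self.roughness():.4g}",
            "=" * 46,
        ]
        return "\n".join(lines)
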