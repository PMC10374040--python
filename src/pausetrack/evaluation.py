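"""Cross-validated envelope reconstruction.

Leave-one-out CV over the speech segments of one (subject, condition, band):
for every lambda on a 50-point log grid from 1e-2 to 1e12, a decoder is
trained on the concatenated training segments (per-segment lagged designs;
no lagged rows span a segment boundary) and scored on the held-out segment;
the lambda maximizing the fold-averaged Pearson r is selected (ties go to
the smaller lambda).  Train and test feature masks may differ, giving the
3 x 3 train-by-test feature grid.

Implementation note: the fold solves work from cached per-segment
cross-products (R'R, R'S, column sums), with the whole lambda grid solved in
one batched factorization, so re-pairings of envelope and EEG (permutation
nulls) and the feature grid reuse almost all of the heavy linear algebra.
The result is numerically identical to fitting each fold directly with
:func:`pausetrack.decoder.fit_decoder`, which the test suite verifies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .datatypes import EEGRecording, EnvelopeSeries, FEATURES
from .decoder import LagSpec, RegularizerM, build_lagged_design, build_regularizer
from .preprocess import ANALYSIS_FS, preprocess_eeg
from .segmentation import PAUSE, SegmentMask, build_feature, detect_pauses, mask_from_intervals
from .stimulus import bandlimit_envelope, downsample_envelope

__all__ = [
    "Segment", "CVPlan", "EvalResult",
    "default_lambda_grid", "run_cv", "feature_grid",
    "truncate_for_duration_match", "run_pauses_removed",
    "segments_from_records",
]


def default_lambda_grid(n: int = 50, low: float = 1e-2, high: float = 1e12
                        ) -> np.ndarray:
    """50 logarithmically spaced regularization values between 0.01 and 1e12."""
    return np.logspace(np.log10(low), np.log10(high), n)


@dataclass
class Segment:
    """One speech segment ready for decoding: band-limited envelope target,
    preprocessed EEG, and the pause/onset/non-onset label mask, all at the
    analysis rate and of equal length."""

    envelope: EnvelopeSeries
    eeg: EEGRecording
    mask: SegmentMask

    def __post_init__(self) -> None:
        n = {self.envelope.n_samples, self.eeg.n_samples, self.mask.n_samples}
        if len(n) != 1:
            raise ValueError(f"segment series lengths differ: {sorted(n)}")

    @property
    def n_samples(self) -> int:
        return self.envelope.n_samples


@dataclass
class CVPlan:
    """Everything one cross-validated evaluation cell needs."""

    segments: List[Segment]
    lag_spec: LagSpec = field(default_factory=LagSpec)
    lambda_grid: np.ndarray = field(default_factory=default_lambda_grid)
    train_feature: str = "full"
    test_feature: str = "full"
    truncation_s: Optional[float] = None
    pauses_removed: bool = False
    subject: str = "S00"
    condition: str = "other"
    band: str = "broadband"

    def __post_init__(self) -> None:
        if len(self.segments) < 2:
            raise ValueError("leave-one-out CV needs at least 2 segments")
        self.lambda_grid = np.asarray(self.lambda_grid, dtype=float)
        if np.any(np.diff(self.lambda_grid) <= 0):
            raise ValueError("lambda_grid must be strictly increasing")
        for f in (self.train_feature, self.test_feature):
            if f not in FEATURES:
                raise ValueError(f"unknown feature {f!r}")


@dataclass
class EvalResult:
    """Per-fold and averaged reconstruction scores at the selected lambda."""

    fold_r: np.ndarray
    fold_mse: np.ndarray
    mean_r: float
    mean_mse: float
    selected_lambda: float
    mean_r_per_lambda: np.ndarray
    lambda_grid: np.ndarray
    n_flagged_folds: int
    subject: str = "S00"
    condition: str = "other"
    band: str = "broadband"
    train_feature: str = "full"
    test_feature: str = "full"
    truncation_s: Optional[float] = None
    pauses_removed: bool = False
    lag_label: str = "0-300ms"


def _feature_valid(seg: Segment, feature: str, pauses_removed: bool) -> np.ndarray:
    valid = build_feature(seg.envelope, seg.mask, feature).valid_mask()
    if pauses_removed:
        valid = valid & (seg.mask.labels != PAUSE)
    return valid


@dataclass
class _Cross:
    """Cross-products of one (design, target, mask) triple."""

    n: int
    A: np.ndarray  # Rv' Rv
    b: np.ndarray  # Rv' Sv
    r1: np.ndarray  # column sums of Rv
    s1: float  # sum of Sv


def _cross(R: np.ndarray, s: np.ndarray, valid: np.ndarray) -> _Cross:
    Rv = R[valid]
    sv = s[valid]
    return _Cross(n=int(valid.sum()), A=Rv.T @ Rv, b=Rv.T @ sv,
                  r1=Rv.sum(axis=0), s1=float(sv.sum()))


def _solve_grid(crosses: Sequence[_Cross], lambdas: np.ndarray,
                M: RegularizerM) -> np.ndarray:
    """Decoder weights for every lambda, from summed training cross-products
    with mean-centering folded in.  Returns (n_lambda, n_features)."""
    N = sum(c.n for c in crosses)
    A = sum(c.A for c in crosses)
    b = sum(c.b for c in crosses)
    r1 = sum(c.r1 for c in crosses)
    s1 = sum(c.s1 for c in crosses)
    Ac = A - np.outer(r1, r1) / N
    bc = b - r1 * (s1 / N)
    systems = Ac[None, :, :] + lambdas[:, None, None] * M.matrix[None, :, :]
    try:
        return np.linalg.solve(systems, bc[None, :, None])[:, :, 0]
    except np.linalg.LinAlgError:
        # some lambdas hit an exactly singular pivot (heavily collinear lag
        # columns at small lambda); solve those by least squares only
        G = np.empty((lambdas.size, bc.size))
        for i in range(lambdas.size):
            try:
                G[i] = np.linalg.solve(systems[i], bc)
            except np.linalg.LinAlgError:
                G[i] = np.linalg.lstsq(systems[i], bc, rcond=None)[0]
        return G


def _score_grid(R_test: np.ndarray, s_test: np.ndarray, valid: np.ndarray,
                G: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Pearson r and MSE for every lambda's weights on one test segment.
    Returns (r, mse), each (n_lambda,), NaN where undefined."""
    L = G.shape[0]
    nv = int(valid.sum())
    if nv < 3:
        return np.full(L, np.nan), np.full(L, np.nan)
    y = s_test[valid]
    if y.std() == 0:
        return np.full(L, np.nan), np.full(L, np.nan)
    X = R_test[valid] @ G.T  # (n_valid, n_lambda)
    xm = X.mean(axis=0)
    ym = y.mean()
    xc = X - xm
    yc = y - ym
    num = xc.T @ yc
    den = np.sqrt((xc ** 2).sum(axis=0) * (yc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / den, np.nan)
    mse = ((X - y[:, None]) ** 2).mean(axis=0)
    return r, mse


def _cv_grid(designs: Sequence[np.ndarray], targets: Sequence[np.ndarray],
             train_valids: Sequence[np.ndarray],
             test_valids: Dict[str, Sequence[np.ndarray]],
             lambdas: np.ndarray, M: RegularizerM,
             pairing: Optional[Sequence[int]] = None,
             cross_cache: Optional[dict] = None,
             ) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    """Leave-one-out CV curves for one train feature and several test features.

    ``pairing[i]`` gives the EEG/design index paired with envelope i
    (identity when None) — the hook the permutation null uses.  A mismatched
    pair whose series differ in length is truncated to the common length.
    Returns, per test-feature key, (fold_r, fold_mse) arrays of shape
    (n_folds, n_lambda).
    """
    n_seg = len(targets)
    if pairing is None:
        pairing = list(range(n_seg))
    if cross_cache is None:
        cross_cache = {}
    out = {key: (np.empty((n_seg, lambdas.size)), np.empty((n_seg, lambdas.size)))
           for key in test_valids}
    for i in range(n_seg):
        key = (i, pairing[i])
        if key not in cross_cache:
            j = pairing[i]
            n = min(targets[i].size, designs[j].shape[0])
            cross_cache[key] = _cross(designs[j][:n], targets[i][:n],
                                      train_valids[i][:n])
    for k in range(n_seg):
        train = [cross_cache[(i, pairing[i])] for i in range(n_seg) if i != k]
        G = _solve_grid(train, lambdas, M)
        j = pairing[k]
        n = min(targets[k].size, designs[j].shape[0])
        for key, valids in test_valids.items():
            r, mse = _score_grid(designs[j][:n], targets[k][:n],
                                 valids[k][:n], G)
            out[key][0][k] = r
            out[key][1][k] = mse
    return out


def _reduce(fold_r: np.ndarray, fold_mse: np.ndarray, lambdas: np.ndarray,
            plan: CVPlan, test_feature: str, lag_label: str) -> EvalResult:
    """Average fold curves, select lambda, package the result."""
    fold_ok = ~np.all(np.isnan(fold_r), axis=1)
    n_flagged = int((~fold_ok).sum())
    if not fold_ok.any():
        raise ValueError("all folds produced undefined scores")
    with np.errstate(invalid="ignore"):
        mean_curve = np.nanmean(fold_r[fold_ok], axis=0)
    if np.all(np.isnan(mean_curve)):
        raise ValueError("no lambda produced a defined mean score")
    idx = int(np.nanargmax(mean_curve))  # first maximum -> smaller lambda on ties
    mean_mse_curve = np.nanmean(fold_mse[fold_ok], axis=0)
    return EvalResult(
        fold_r=fold_r[:, idx], fold_mse=fold_mse[:, idx],
        mean_r=float(mean_curve[idx]), mean_mse=float(mean_mse_curve[idx]),
        selected_lambda=float(lambdas[idx]), mean_r_per_lambda=mean_curve,
        lambda_grid=lambdas, n_flagged_folds=n_flagged,
        subject=plan.subject, condition=plan.condition, band=plan.band,
        train_feature=plan.train_feature, test_feature=test_feature,
        truncation_s=plan.truncation_s, pauses_removed=plan.pauses_removed,
        lag_label=lag_label,
    )


def _lag_label(spec: LagSpec) -> str:
    return f"{spec.lag_min_ms:.0f}-{spec.lag_max_ms:.0f}ms"


def run_cv(plan: CVPlan, pairing: Optional[Sequence[int]] = None,
           designs: Optional[Sequence[np.ndarray]] = None,
           cross_cache: Optional[dict] = None) -> EvalResult:
    """Leave-one-out cross-validation with lambda selection for one cell."""
    if designs is None:
        designs = [build_lagged_design(s.eeg, plan.lag_spec) for s in plan.segments]
    targets = [s.envelope.values for s in plan.segments]
    train_valids = [_feature_valid(s, plan.train_feature, plan.pauses_removed)
                    for s in plan.segments]
    test_valids = {plan.test_feature:
                   [_feature_valid(s, plan.test_feature, plan.pauses_removed)
                    for s in plan.segments]}
    M = build_regularizer(plan.lag_spec, plan.segments[0].eeg.n_channels)
    curves = _cv_grid(designs, targets, train_valids, test_valids,
                      plan.lambda_grid, M, pairing=pairing,
                      cross_cache=cross_cache)
    fold_r, fold_mse = curves[plan.test_feature]
    return _reduce(fold_r, fold_mse, plan.lambda_grid, plan,
                   plan.test_feature, _lag_label(plan.lag_spec))


def feature_grid(plan: CVPlan) -> Dict[Tuple[str, str], EvalResult]:
    """All nine (train, test) feature combinations with shared folds; lambda
    is selected per cell."""
    designs = [build_lagged_design(s.eeg, plan.lag_spec) for s in plan.segments]
    targets = [s.envelope.values for s in plan.segments]
    M = build_regularizer(plan.lag_spec, plan.segments[0].eeg.n_channels)
    test_valids = {f: [_feature_valid(s, f, plan.pauses_removed)
                       for s in plan.segments] for f in FEATURES}
    results: Dict[Tuple[str, str], EvalResult] = {}
    for train in FEATURES:
        cell_plan = replace(plan, train_feature=train)
        train_valids = test_valids[train]
        curves = _cv_grid(designs, targets, train_valids, test_valids,
                          plan.lambda_grid, M)
        for test in FEATURES:
            fold_r, fold_mse = curves[test]
            results[(train, test)] = _reduce(fold_r, fold_mse,
                                             plan.lambda_grid, cell_plan, test,
                                             _lag_label(plan.lag_spec))
    return results


def truncate_for_duration_match(plan: CVPlan, seconds: float) -> CVPlan:
    """Truncate every segment to its first ``seconds`` so all conditions carry
    identical data durations into CV."""
    new_segments = []
    for seg in plan.segments:
        n = int(round(seconds * seg.envelope.fs))
        if seg.n_samples < n:
            raise ValueError(
                f"segment of {seg.n_samples / seg.envelope.fs:.1f} s shorter "
                f"than requested {seconds} s")
        env = EnvelopeSeries(values=seg.envelope.values[:n], fs=seg.envelope.fs,
                             band=seg.envelope.band,
                             valid=None if seg.envelope.valid is None
                             else seg.envelope.valid[:n],
                             provenance=seg.envelope.provenance)
        eeg = seg.eeg.copy_with(data=seg.eeg.data[:, :n])
        mask = SegmentMask(labels=seg.mask.labels[:n], fs=seg.mask.fs,
                           onset_window_ms=seg.mask.onset_window_ms,
                           threshold=seg.mask.threshold,
                           min_pause_ms=seg.mask.min_pause_ms)
        new_segments.append(Segment(envelope=env, eeg=eeg, mask=mask))
    return replace(plan, segments=new_segments, truncation_s=seconds)


def run_pauses_removed(plan: CVPlan,
                       lag_specs: Sequence[LagSpec] = (),
                       ) -> Dict[str, EvalResult]:
    """Pause-removed decoding: pause-labelled samples are dropped from the
    fit and the score (rows of the lagged design at those indices are
    deleted), run for each requested lag window (default 0-300 and 0-500 ms)."""
    if not lag_specs:
        fs = plan.lag_spec.fs
        lag_specs = (LagSpec(0.0, 300.0, fs), LagSpec(0.0, 500.0, fs))
    out: Dict[str, EvalResult] = {}
    for spec in lag_specs:
        sub = replace(plan, lag_spec=spec, pauses_removed=True)
        out[_lag_label(spec)] = run_cv(sub)
    return out


def segments_from_records(records, band: str, fs_out: float = ANALYSIS_FS,
                          use_truth_mask: bool = True,
                          threshold_frac: float = 0.01,
                          min_pause_ms: float = 100.0) -> List[Segment]:
    """Bring synthetic records (or any (envelope, boundaries, eeg) triples)
    to analysis form for one band: preprocess the EEG, band-limit the
    envelope, build the segment mask (from generator ground truth or by
    threshold detection), and align lengths."""
    segments = []
    for rec in records:
        eeg = preprocess_eeg(rec.eeg, band, fs_out)
        env_band = bandlimit_envelope(rec.envelope, band, fs_out)
        env_128 = downsample_envelope(rec.envelope, fs_out)
        if use_truth_mask and rec.truth is not None and rec.truth.pause_intervals:
            mask = mask_from_intervals(rec.truth.pause_intervals,
                                       env_128.n_samples, fs_out)
        else:
            mask = detect_pauses(env_128, threshold_frac=threshold_frac,
                                 min_pause_ms=min_pause_ms)
        n = min(eeg.n_samples, env_band.n_samples, mask.n_samples)
        eeg = eeg.copy_with(data=eeg.data[:, :n])
        env_band = EnvelopeSeries(values=env_band.values[:n], fs=fs_out,
                                  band=band)
        mask = SegmentMask(labels=mask.labels[:n], fs=fs_out,
                           onset_window_ms=mask.onset_window_ms,
                           threshold=mask.threshold,
                           min_pause_ms=mask.min_pause_ms)
        segments.append(Segment(envelope=env_band, eeg=eeg, mask=mask))
    return segments
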