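"""Per-timepoint classification with temporal generalization.

A separate L2-regularized logistic regression (C = 1) is fit at every
time sample on the channel vector of each trial; a temporal
generalization matrix (TGM) scores each trained model at every test
time, so the diagonal reflects time-locked decoding and off-diagonal
cells temporal transfer of the neural code.  Within a vigilance state,
scores come from two-fold stratified cross-validation; across states
the decoder is fit on all (balanced) training-state epochs and scored
on all test-state epochs, which are disjoint recordings.

Test trials are standardized per trial (each trial carries its own
mean/scale), so no training-set statistics leak into scoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from sklearn.covariance import LedoitWolf
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .containers import ChannelLayout, EpochSet
from .preprocess import lowpass_filter, standardize_trials

__all__ = [
    "ClassifierSpec",
    "FittedDecoder",
    "TemporalGeneralizationMatrix",
    "fit_timepoint",
    "fit_decoder",
    "temporal_generalization",
    "within_state_tgm",
    "cross_state_tgm",
    "peak_window_summary",
    "prepare_for_decoding",
    "permute_labels",
]


@dataclass(frozen=True)
class ClassifierSpec:
    """L2-penalized logistic regression settings (default C = 1)."""

    C: float = 1.0
    fit_intercept: bool = True
    max_iter: int = 2000
    tol: float = 1e-8
    #: any sklearn solver for the L2 logistic objective; the problem is
    #: strictly convex, so the choice affects speed only.  Exact Newton
    #: is fastest at EEG-typical trial/channel counts.
    solver: str = "newton-cholesky"

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be > 0")


@dataclass
class TemporalGeneralizationMatrix:
    """Train-time x test-time accuracy grid for one subject and state pair."""

    scores: np.ndarray
    train_times: np.ndarray
    test_times: np.ndarray
    train_state: str
    test_state: str
    subject: int
    n_folds: int
    contrast: Optional[str] = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.train_times), len(self.test_times)):
            raise ValueError("scores shape must match the time axes")
        if self.scores.min() < 0 or self.scores.max() > 1:
            raise ValueError("accuracies must lie in [0, 1]")


@dataclass
class FittedDecoder:
    """Per-train-time weights/intercepts plus what the forward model needs.

    ``covariances`` holds the per-timepoint channel covariance of the
    training data (Ledoit-Wolf shrunk); ``scale_summary`` the mean
    per-channel standardization scale of the training trials, used to
    restore µV units on activation patterns.
    """

    weights: np.ndarray      # (n_times, n_channels)
    intercepts: np.ndarray   # (n_times,)
    train_times: np.ndarray
    layout: ChannelLayout
    state: str
    subject: int
    contrast: Optional[str] = None
    covariances: Optional[np.ndarray] = None  # (n_times, n_ch, n_ch)
    scale_summary: Optional[np.ndarray] = None  # (n_channels,)


def fit_timepoint(
    X: np.ndarray, y: np.ndarray, spec: ClassifierSpec = ClassifierSpec()
) -> tuple[np.ndarray, float]:
    """Fit one L2 logistic regression on trials x channels data.

    Minimizes ``0.5 ||w||^2 + C * sum_i log(1 + exp(-y_i (w.x_i + b)))``
    with y in {-1, +1}; the decision rule is sign(w.x + b) with ties
    (exactly 0) assigned to class 1.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be trials x channels matching y")
    if not np.all(np.isfinite(X)):
        raise ValueError("X must be finite")
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    # sklearn's default penalty is L2 with strength 1/C
    clf = LogisticRegression(
        C=spec.C, fit_intercept=spec.fit_intercept,
        solver=spec.solver, max_iter=spec.max_iter, tol=spec.tol,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            clf.fit(X, y)
        except ConvergenceWarning as err:
            raise RuntimeError(
                f"logistic fit did not converge in {spec.max_iter} iterations "
                f"(n={X.shape[0]}, p={X.shape[1]}): {err}"
            ) from err
    b = float(clf.intercept_[0]) if spec.fit_intercept else 0.0
    return clf.coef_.ravel().copy(), b


def prepare_for_decoding(
    epochs: EpochSet, lowpass: Optional[float] = 25.0
) -> EpochSet:
    """Decode-time conditioning: optional low-pass, then per-trial
    standardization (storing the removed means/scales for µV recovery)."""
    ep = lowpass_filter(epochs, lowpass) if lowpass is not None else epochs
    return standardize_trials(ep)


def fit_decoder(
    epochs: EpochSet,
    spec: ClassifierSpec = ClassifierSpec(),
    estimate_covariance: bool = False,
) -> FittedDecoder:
    """Fit one classifier per time sample of an (already prepared) EpochSet.

    With ``estimate_covariance`` the per-timepoint training-data channel
    covariance (Ledoit-Wolf shrinkage toward the diagonal, stable when
    channels outnumber trials) is retained for the forward model.
    """
    n_t = epochs.n_samples
    W = np.empty((n_t, epochs.n_channels))
    b = np.empty(n_t)
    covs = np.empty((n_t, epochs.n_channels, epochs.n_channels)) if estimate_covariance else None
    for t in range(n_t):
        Xt = epochs.data[:, :, t]
        W[t], b[t] = fit_timepoint(Xt, epochs.labels, spec)
        if covs is not None:
            covs[t] = LedoitWolf(assume_centered=False).fit(Xt).covariance_
    rec = epochs.standardization
    return FittedDecoder(
        weights=W, intercepts=b, train_times=epochs.times.copy(),
        layout=epochs.layout, state=epochs.state, subject=epochs.subject,
        contrast=epochs.contrast, covariances=covs,
        scale_summary=None if rec is None else rec.channel_scale_summary,
    )


def temporal_generalization(
    decoder: FittedDecoder, test: EpochSet
) -> TemporalGeneralizationMatrix:
    """Score every trained timepoint model at every test timepoint.

    scores[i, j] is the fraction of test trials correctly classified by
    the model trained at time i using the channel vector at time j.
    """
    if test.n_channels != decoder.weights.shape[1] or (
        test.layout.names != decoder.layout.names
    ):
        raise ValueError("test channels do not match the trained decoder")
    # logits: (train_times, trials, test_times)
    logits = np.tensordot(decoder.weights, test.data, axes=([1], [1]))
    logits += decoder.intercepts[:, None, None]
    pred = (logits >= 0).astype(int)  # tie on the boundary -> class 1
    correct = pred == test.labels[None, :, None]
    scores = correct.mean(axis=1)
    return TemporalGeneralizationMatrix(
        scores=scores,
        train_times=decoder.train_times.copy(),
        test_times=test.times.copy(),
        train_state=decoder.state,
        test_state=test.state,
        subject=test.subject,
        n_folds=1,
        contrast=test.contrast,
    )


def within_state_tgm(
    epochs: EpochSet,
    spec: ClassifierSpec = ClassifierSpec(),
    seed: int = 0,
    return_decoders: bool = False,
    estimate_covariance: bool = False,
):
    """Two-fold stratified cross-validated TGM within one state.

    Each fold's decoder is scored on the held-out half; the two fold
    matrices are averaged with equal weight.  The fold split is
    deterministic given ``seed``.
    """
    labels = epochs.labels
    if min((labels == 0).sum(), (labels == 1).sum()) < 2:
        raise ValueError("need >= 2 trials per class for 2-fold CV")
    skf = StratifiedKFold(n_splits=2, shuffle=True, random_state=int(seed))
    fold_scores = []
    decoders = []
    for train_idx, test_idx in skf.split(np.zeros(epochs.n_trials), labels):
        train = _subset(epochs, train_idx)
        test = _subset(epochs, test_idx)
        dec = fit_decoder(train, spec, estimate_covariance=estimate_covariance)
        fold_scores.append(temporal_generalization(dec, test).scores)
        decoders.append(dec)
    tgm = TemporalGeneralizationMatrix(
        scores=np.mean(fold_scores, axis=0),
        train_times=epochs.times.copy(),
        test_times=epochs.times.copy(),
        train_state=epochs.state,
        test_state=epochs.state,
        subject=epochs.subject,
        n_folds=2,
        contrast=epochs.contrast,
    )
    if return_decoders:
        return tgm, decoders
    return tgm


def cross_state_tgm(
    train: EpochSet,
    test: EpochSet,
    spec: ClassifierSpec = ClassifierSpec(),
    return_decoder: bool = False,
    estimate_covariance: bool = False,
):
    """Transfer TGM: fit on all training-state epochs, score on all
    test-state epochs.  The two states are disjoint recordings, so no
    cross-validation is involved."""
    if train.state == test.state:
        raise ValueError("states must differ (use within_state_tgm)")
    dec = fit_decoder(train, spec, estimate_covariance=estimate_covariance)
    tgm = temporal_generalization(dec, test)
    if return_decoder:
        return tgm, dec
    return tgm


def peak_window_summary(
    tgm: TemporalGeneralizationMatrix, window: tuple[float, float]
) -> float:
    """Mean accuracy over cells whose train AND test times fall in the
    closed window (the 250-400 ms peak-window summary statistic)."""
    lo, hi = window
    tr = (tgm.train_times >= lo - 1e-9) & (tgm.train_times <= hi + 1e-9)
    te = (tgm.test_times >= lo - 1e-9) & (tgm.test_times <= hi + 1e-9)
    if not (tr.any() and te.any()):
        raise ValueError("window contains no cells")
    return float(tgm.scores[np.ix_(tr, te)].mean())


def permute_labels(epochs: EpochSet, seed: int) -> EpochSet:
    """Label-permuted copy (the within-subject permutation null)."""
    rng = np.random.default_rng(seed)
    return epochs.evolve(
        labels=rng.permutation(epochs.labels),
        log=epochs.log + [f"permute_labels(seed={seed})"],
    )


def _subset(epochs: EpochSet, idx: np.ndarray) -> EpochSet:
    rec = epochs.standardization
    return epochs.evolve(
        data=epochs.data[idx],
        labels=epochs.labels[idx],
        standardization=None if rec is None else type(rec)(
            means=rec.means[idx], scales=rec.scales[idx], flagged=rec.flagged[idx]
        ),
    )
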