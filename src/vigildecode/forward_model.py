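"""Backward-to-forward model conversion of classifier weights.

A linear decoder's weight vector w is a backward (extraction) filter:
it may load heavily on noise channels whose only job is to cancel
signal-unrelated variance, so w itself is not interpretable as a scalp
distribution.  For a single linear filter the corresponding forward
(activation) pattern is

    a = (Sigma_x w) / (w' Sigma_x w)

where Sigma_x is the data covariance; a describes how the decoded
latent source projects onto the sensors and has the units of the data.
Multiplying each channel by the (training-set mean of the) per-trial
standardization scale restores microvolts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .containers import ChannelLayout
from .decoding import FittedDecoder

__all__ = [
    "TopographyMap",
    "haufe_transform",
    "unstandardize",
    "pattern_timecourse",
    "mean_topography",
]


@dataclass
class TopographyMap:
    """Forward-model activation patterns, channels x train-time, in µV."""

    patterns: np.ndarray
    times: np.ndarray
    layout: ChannelLayout
    state: str
    contrast: Optional[str] = None
    units: str = "uV"

    def __post_init__(self) -> None:
        self.patterns = np.asarray(self.patterns, dtype=float)
        if self.patterns.shape != (self.layout.n_channels, len(self.times)):
            raise ValueError("patterns must be channels x times matching layout")
        if not np.all(np.isfinite(self.patterns)):
            raise ValueError("patterns must be finite")


def haufe_transform(w: np.ndarray, sigma_x: np.ndarray) -> np.ndarray:
    """Activation pattern a = Sigma_x w / (w' Sigma_x w).

    The scalar denominator is the latent-source variance of the single
    filter, so ``a`` carries the units of the data.
    """
    w = np.asarray(w, dtype=float).ravel()
    sigma_x = np.asarray(sigma_x, dtype=float)
    n = w.size
    if sigma_x.shape != (n, n):
        raise ValueError("sigma_x must be n_channels x n_channels")
    if not np.allclose(sigma_x, sigma_x.T, rtol=1e-8, atol=1e-10):
        raise ValueError("sigma_x must be symmetric")
    num = sigma_x @ w
    denom = float(w @ num)
    if denom <= 0:
        raise ValueError("degenerate filter: w' Sigma w must be > 0")
    return num / denom


def unstandardize(pattern: np.ndarray, channel_scales: np.ndarray) -> np.ndarray:
    """Restore µV by multiplying each channel with its standardization
    scale summary (training-set mean of the per-trial scales)."""
    pattern = np.asarray(pattern, dtype=float)
    channel_scales = np.asarray(channel_scales, dtype=float)
    if channel_scales.shape != pattern.shape[:1]:
        raise ValueError("scale summary must have one entry per channel")
    return pattern * channel_scales


def pattern_timecourse(decoder: FittedDecoder) -> TopographyMap:
    """Forward-model activation pattern at every training time point.

    The normalized pattern a = Sigma w / (w' Sigma w) is rescaled by
    the latent-source SD sqrt(w' Sigma w), giving Sigma w / sqrt(w'
    Sigma w): invariant to the arbitrary scale of the filter and, for a
    clean planted source, equal to that source's per-class deviation at
    the sensors.  Requires the decoder to carry per-timepoint training
    covariances; if a standardization scale summary is present the
    pattern is returned in µV, otherwise in standardized units.
    """
    if decoder.covariances is None:
        raise ValueError("decoder carries no training covariances")
    n_t = decoder.weights.shape[0]
    patterns = np.empty((decoder.weights.shape[1], n_t))
    for t in range(n_t):
        w, sigma = decoder.weights[t], decoder.covariances[t]
        a = haufe_transform(w, sigma) * np.sqrt(w @ sigma @ w)
        if decoder.scale_summary is not None:
            a = unstandardize(a, decoder.scale_summary)
        patterns[:, t] = a
    return TopographyMap(
        patterns=patterns,
        times=decoder.train_times.copy(),
        layout=decoder.layout,
        state=decoder.state,
        contrast=decoder.contrast,
        units="uV" if decoder.scale_summary is not None else "standardized",
    )


def mean_topography(maps: Sequence[TopographyMap]) -> TopographyMap:
    """Average activation maps (e.g. across CV folds or subjects)."""
    if not maps:
        raise ValueError("no maps to average")
    first = maps[0]
    for m in maps[1:]:
        if m.patterns.shape != first.patterns.shape:
            raise ValueError("maps must share shape")
    return TopographyMap(
        patterns=np.mean([m.patterns for m in maps], axis=0),
        times=first.times.copy(),
        layout=first.layout,
        state=first.state,
        contrast=first.contrast,
        units=first.units,
    )
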