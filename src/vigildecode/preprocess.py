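"""Trial conditioning: filtering, re-cropping, decimation, per-trial
standardization, and balanced epoch subsampling.

The canonical order, asserted downstream, is::

    bandpass (1-20 Hz FIR) -> crop (-0.2..1.0 s) -> decimate (x4)
    -> balance (100/condition) -> [decode time] lowpass 25 Hz -> standardize

Decimation is plain sample-picking: the preceding 1-20 Hz band-pass
already confines the signal below the post-decimation Nyquist, so no
extra anti-alias stage is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from mne.filter import filter_data

from .containers import EpochSet, StandardizationRecord

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessingParams",
    "bandpass_filter",
    "lowpass_filter",
    "crop",
    "decimate",
    "standardize_trials",
    "unstandardize_trials",
    "balance_epochs",
    "preprocess",
    "artifact_correction_hook",
]


@dataclass(frozen=True)
class PreprocessingParams:
    """Knobs of the trial-conditioning stage (defaults = study values)."""

    bandpass: tuple[float, float] = (1.0, 20.0)
    crop_window: tuple[float, float] = (-0.2, 1.0)
    decim: int = 4
    lowpass: Optional[float] = 25.0  # applied at decode time; None skips
    n_balance: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.decim < 1:
            raise ValueError("decim must be >= 1")
        if self.n_balance < 2:
            raise ValueError("n_balance must be >= 2")
        if self.crop_window[0] >= self.crop_window[1]:
            raise ValueError("crop_window must be a proper interval")


def bandpass_filter(epochs: EpochSet, low: float, high: float) -> EpochSet:
    """Zero-phase FIR band-pass applied per channel per trial.

    Windowed-sinc (Hamming) design with mne's default transition bands
    (25% of each edge frequency, floor 2 Hz).
    """
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    if high >= epochs.sfreq / 2:
        raise ValueError("high edge must be below Nyquist")
    out = filter_data(
        epochs.data, epochs.sfreq, l_freq=low, h_freq=high,
        method="fir", phase="zero", fir_window="hamming", fir_design="firwin",
        verbose="error",
    )
    ep = epochs.evolve(data=out, log=epochs.log + [f"bandpass({low}, {high})"])
    return ep


def lowpass_filter(epochs: EpochSet, high: float) -> EpochSet:
    """Zero-phase FIR low-pass (the decode-time 25 Hz smoothing)."""
    if not 0 < high < epochs.sfreq / 2:
        raise ValueError("lowpass edge must be in (0, Nyquist)")
    out = filter_data(
        epochs.data, epochs.sfreq, l_freq=None, h_freq=high,
        method="fir", phase="zero", fir_window="hamming", fir_design="firwin",
        verbose="error",
    )
    return epochs.evolve(data=out, log=epochs.log + [f"lowpass({high})"])


def crop(epochs: EpochSet, window: tuple[float, float]) -> EpochSet:
    """Retain samples with window[0] <= t <= window[1] (closed interval)."""
    lo, hi = window
    mask = (epochs.times >= lo - 1e-9) & (epochs.times <= hi + 1e-9)
    if not mask.any():
        raise ValueError("crop window contains no samples")
    return epochs.evolve(
        data=epochs.data[:, :, mask],
        times=epochs.times[mask],
        log=epochs.log + [f"crop({lo}, {hi})"],
    )


def decimate(epochs: EpochSet, factor: int) -> EpochSet:
    """Keep every ``factor``-th sample starting at the first.

    No anti-alias filter is applied here; the pipeline guarantees the
    band-pass precedes decimation.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return epochs.evolve(log=epochs.log + ["decimate(1)"])
    return epochs.evolve(
        data=epochs.data[:, :, ::factor],
        times=epochs.times[::factor],
        sfreq=epochs.sfreq / factor,
        log=epochs.log + [f"decimate({factor})"],
    )


def standardize_trials(epochs: EpochSet) -> EpochSet:
    """Remove the mean and scale to unit variance per trial per channel.

    The scale is the population SD over time samples.  Zero-variance
    trial-channels get scale 1 (mean still removed) and are flagged.
    The removed (mean, scale) pairs are stored on the returned EpochSet
    so the transform can be inverted for µV recovery.
    """
    if epochs.n_samples < 2:
        raise ValueError("need >= 2 samples per trial to standardize")
    means = epochs.data.mean(axis=-1)
    sds = epochs.data.std(axis=-1)  # population (divide by N)
    flagged = sds <= np.finfo(float).tiny
    if flagged.any():
        logger.warning(
            "standardize_trials: %d zero-variance trial-channel(s); scale forced to 1",
            int(flagged.sum()),
        )
    scales = np.where(flagged, 1.0, sds)
    out = (epochs.data - means[:, :, None]) / scales[:, :, None]
    record = StandardizationRecord(means=means, scales=scales, flagged=flagged)
    return epochs.evolve(
        data=out, standardization=record, log=epochs.log + ["standardize"]
    )


def unstandardize_trials(epochs: EpochSet) -> EpochSet:
    """Invert standardize_trials using the stored record."""
    rec = epochs.standardization
    if rec is None:
        raise ValueError("no standardization record on this EpochSet")
    out = epochs.data * rec.scales[:, :, None] + rec.means[:, :, None]
    return epochs.evolve(
        data=out, standardization=None, log=epochs.log + ["unstandardize"]
    )


def balance_epochs(epochs: EpochSet, n: int, seed: int) -> EpochSet:
    """Subsample to an equal number of trials per condition.

    Each condition contributes min(n, smaller condition count) trials,
    drawn without replacement (class 0 first, then class 1, so the draw
    is reproducible), preserving original trial order within the
    result.  Capping both classes at the smaller count keeps the chance
    level at exactly 50% even when one condition is short (the N1-style
    "all available epochs" branch).
    """
    counts = [(epochs.labels == c).sum() for c in (0, 1)]
    if min(counts) == 0:
        raise ValueError("both conditions must have at least one trial")
    k = min(n, *counts)
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for c in (0, 1):
        idx = np.flatnonzero(epochs.labels == c)
        keep.append(rng.choice(idx, size=k, replace=False))
    sel = np.sort(np.concatenate(keep))
    return epochs.evolve(
        data=epochs.data[sel],
        labels=epochs.labels[sel],
        log=epochs.log + [f"balance(n={n}, kept={k}/condition, seed={seed})"],
    )


def artifact_correction_hook(epochs: EpochSet) -> EpochSet:
    """Placeholder for ICA-style artifact correction on real recordings.

    Synthetic data are artifact-free by construction, so this is a
    logged no-op; real-data users can substitute their own callable of
    the same signature in the pipeline.
    """
    return epochs.evolve(log=epochs.log + ["artifact_correction(noop)"])


def preprocess(epochs: EpochSet, params: PreprocessingParams) -> EpochSet:
    """Apply the fixed conditioning order: bandpass -> crop -> decimate
    -> balance.  (The decode-time low-pass and standardization are
    applied by the decoding stage.)"""
    ep = bandpass_filter(epochs, *params.bandpass)
    ep = crop(ep, params.crop_window)
    ep = decimate(ep, params.decim)
    ep = balance_epochs(ep, params.n_balance, params.seed)
    return ep
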