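"""Shared data containers for epoched EEG and channel geometry.

Conventions used throughout the package:

* data arrays are ``trials x channels x samples`` in microvolts (µV),
* ``times`` is in seconds relative to stimulus onset,
* condition labels are binary: 0 = baseline category (familiar voice /
  own name), 1 = deviant category (unfamiliar voice / other name),
* channel positions live on a 2-D unit head disc with +y pointing
  anterior (toward the nose).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

#: Vigilance states in canonical (wake-to-sleep-depth, then REM) order.
STATES = ("WAKE", "N1", "N2", "N3", "REM")

#: The two binary stimulus contrasts: voice familiarity and own/other name.
CONTRASTS = ("VOICE", "NAME")

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass(frozen=True)
class ChannelLayout:
    """2-D sensor geometry on the unit head disc.

    Parameters
    ----------
    positions : (n_channels, 2) array
        Channel coordinates; all must lie within the unit disc.
    names : tuple of str
        Unique channel identifiers, one per position.
    """

    positions: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2 or pos.shape[0] == 0:
            raise ValueError("positions must be a non-empty (n, 2) array")
        if len(self.names) != pos.shape[0]:
            raise ValueError("names and positions disagree in length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("channel names must be unique")
        if np.any(np.linalg.norm(pos, axis=1) > 1.0 + 1e-9):
            raise ValueError("channel positions must lie within the unit disc")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "names", tuple(self.names))

    @property
    def n_channels(self) -> int:
        return self.positions.shape[0]

    @classmethod
    def default(cls, n_channels: int = 173) -> "ChannelLayout":
        """Deterministic sunflower (golden-angle spiral) montage.

        A generic stand-in for a reduced high-density net: channels cover
        the disc quasi-uniformly.  The default count of 173 matches a
        256-electrode net with cheek/neck channels removed.
        """
        if n_channels < 1:
            raise ValueError("n_channels must be positive")
        idx = np.arange(n_channels)
        radius = 0.95 * np.sqrt((idx + 0.5) / n_channels)
        theta = idx * _GOLDEN_ANGLE
        pos = np.column_stack([radius * np.cos(theta), radius * np.sin(theta)])
        names = tuple(f"E{i + 1}" for i in idx)
        return cls(pos, names)

    def nearest(self, point: Sequence[float]) -> int:
        """Index of the channel nearest to a 2-D point."""
        d = np.linalg.norm(self.positions - np.asarray(point, float), axis=1)
        return int(np.argmin(d))


@dataclass(frozen=True)
class StandardizationRecord:
    """Per-(trial, channel) mean and scale removed by standardization.

    ``scales`` holds the population standard deviation over time samples,
    except for flagged degenerate (zero-variance) entries where the scale
    was forced to 1 so that the transform stays invertible.
    """

    means: np.ndarray   # (trials, channels)
    scales: np.ndarray  # (trials, channels)
    flagged: np.ndarray  # (trials, channels) bool: zero-variance entries

    @property
    def channel_scale_summary(self) -> np.ndarray:
        """Mean per-channel scale across trials (for µV recovery)."""
        return self.scales.mean(axis=0)


@dataclass
class EpochSet:
    """One subject-state block of epoched EEG.

    ``data`` is trials x channels x samples in µV (or standardized units
    once ``standardization`` is set).  ``log`` records the processing
    steps applied, in order.
    """

    data: np.ndarray
    times: np.ndarray
    labels: np.ndarray
    state: str
    subject: int
    sfreq: float
    layout: ChannelLayout
    contrast: Optional[str] = None
    standardization: Optional[StandardizationRecord] = None
    log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        n_trials, n_ch, n_samp = self.data.shape
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data must be finite")
        if self.times.shape != (n_samp,):
            raise ValueError("times length must match the sample axis")
        if self.labels.shape != (n_trials,):
            raise ValueError("labels length must match the trial axis")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary (0/1)")
        if n_ch != self.layout.n_channels:
            raise ValueError("channel axis does not match layout")
        if n_samp > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(dt, 1.0 / self.sfreq, rtol=1e-6, atol=1e-9):
                raise ValueError("times spacing must equal 1/sfreq")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def copy(self) -> "EpochSet":
        return EpochSet(
            data=self.data.copy(),
            times=self.times.copy(),
            labels=self.labels.copy(),
            state=self.state,
            subject=self.subject,
            sfreq=self.sfreq,
            layout=self.layout,
            contrast=self.contrast,
            standardization=self.standardization,
            log=list(self.log),
        )

    def evolve(self, **changes) -> "EpochSet":
        """Return a shallow-modified copy (dataclasses.replace wrapper)."""
        return replace(self, **changes)
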