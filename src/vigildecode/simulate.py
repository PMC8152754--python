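"""Synthetic multi-subject, multi-state epoched EEG with planted effects.

The generator emulates the statistical structure that the decoding
analysis assumes: per-vigilance-state background activity (1/f "pink"
noise, a state-characteristic oscillation, and broadband sensor noise)
plus, in selected states, a condition difference that is separable in
space (a fronto-central Gaussian topography) and time (an evoked
envelope peaking at 250-400 ms that reverses polarity around 0.6 s,
i.e. a K-complex-like biphasic wave).  The class difference is added to
the deviant category (label 1, unfamiliar voice / other name), which in
this paradigm elicits the larger response.

Everything is deterministic given the configuration seed; per-subject
amplitude and topography-center jitter model between-subject
variability of the evoked pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.interpolate import PchipInterpolator

from .containers import CONTRASTS, STATES, ChannelLayout, EpochSet

__all__ = [
    "EffectSpec",
    "NoiseSpec",
    "SimulationConfig",
    "default_noise_specs",
    "generate_topography",
    "generate_effect_timecourse",
    "simulate_background",
    "simulate_epochs",
]


@dataclass(frozen=True)
class EffectSpec:
    """Planted condition-difference pattern for one binary contrast.

    amplitude is the condition-mean difference in µV at the topography
    maximum and envelope peak; sign +1 adds the positive lobe to the
    deviant class (label 1).
    """

    topography_center: tuple[float, float] = (0.0, 0.35)  # fronto-central
    topography_spread: float = 0.45
    peak_window: tuple[float, float] = (0.25, 0.40)
    reversal_time: float = 0.6
    amplitude: float = 5.0
    shared_states: frozenset[str] = frozenset({"N2", "N3"})
    sign: float = 1.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.topography_spread <= 0:
            raise ValueError("topography_spread must be > 0")
        lo, hi = self.peak_window
        if not lo < hi:
            raise ValueError("peak_window must be a proper interval")
        if self.reversal_time <= hi:
            raise ValueError("reversal_time must lie after the peak window")
        object.__setattr__(self, "shared_states", frozenset(self.shared_states))


#: Characteristic oscillation frequency (Hz) per vigilance state:
#: wake alpha, N1 slowed alpha/theta, N2 spindle band, N3 slow waves,
#: REM theta.
_STATE_OSC_FREQ = {"WAKE": 10.0, "N1": 7.0, "N2": 13.0, "N3": 1.5, "REM": 6.0}
_STATE_OSC_AMP = {"WAKE": 4.0, "N1": 2.5, "N2": 3.0, "N3": 15.0, "REM": 2.5}
_STATE_PINK_SD = {"WAKE": 8.0, "N1": 9.0, "N2": 10.0, "N3": 18.0, "REM": 8.0}


@dataclass(frozen=True)
class NoiseSpec:
    """State-specific background: pink + oscillation + white, all in µV."""

    state: str
    pink_exponent: float = 1.0
    pink_sd: float = 10.0
    oscillation_freq: float = 10.0
    oscillation_amp: float = 3.0
    white_sd: float = 2.0

    def __post_init__(self) -> None:
        if min(self.pink_sd, self.oscillation_amp, self.white_sd) < 0:
            raise ValueError("noise amplitudes must be >= 0")
        if self.oscillation_freq < 0:
            raise ValueError("oscillation_freq must be >= 0")


def state_noise_sd(spec: NoiseSpec) -> float:
    """Per-sample background SD implied by a NoiseSpec (µV): pink,
    oscillation (amp/sqrt(2)) and white components add in quadrature."""
    return float(np.sqrt(
        spec.pink_sd**2 + spec.oscillation_amp**2 / 2.0 + spec.white_sd**2
    ))


def default_noise_specs() -> dict[str, NoiseSpec]:
    return {
        s: NoiseSpec(
            state=s,
            pink_sd=_STATE_PINK_SD[s],
            oscillation_freq=_STATE_OSC_FREQ[s],
            oscillation_amp=_STATE_OSC_AMP[s],
        )
        for s in STATES
    }


def default_effect_specs() -> dict[str, EffectSpec]:
    """Planted contrasts: VOICE decodable in N2/N3, NAME in WAKE and
    (more weakly) N3, mirroring where the respective effects were found."""
    return {
        "VOICE": EffectSpec(amplitude=5.0, shared_states=frozenset({"N2", "N3"})),
        "NAME": EffectSpec(amplitude=3.0, shared_states=frozenset({"WAKE", "N3"})),
    }


@dataclass
class SimulationConfig:
    """Full description of one synthetic study.

    Defaults mirror the emulated study: 16 subjects, five vigilance
    states, 250 Hz acquisition, 5 s epochs from 2 s before to 3 s after
    stimulus onset, 173-channel reduced montage, and fewer available N1
    epochs than the 100-epoch balancing target.
    """

    n_subjects: int = 16
    states: tuple[str, ...] = STATES
    n_epochs_per_condition: dict[str, int] = field(
        default_factory=lambda: {s: (40 if s == "N1" else 120) for s in STATES}
    )
    sfreq: float = 250.0
    epoch_window: tuple[float, float] = (-2.0, 3.0)
    layout: ChannelLayout = field(default_factory=ChannelLayout.default)
    effects: dict[str, EffectSpec] = field(default_factory=default_effect_specs)
    noise: dict[str, NoiseSpec] = field(default_factory=default_noise_specs)
    subject_variability: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        lo, hi = self.epoch_window
        if not (lo <= -0.2 and hi >= 1.0):
            raise ValueError("epoch_window must contain the -0.2..1.0 s analysis window")
        if isinstance(self.n_epochs_per_condition, int):
            n = self.n_epochs_per_condition
            self.n_epochs_per_condition = {s: n for s in self.states}
        for s in self.states:
            if s not in self.noise:
                raise ValueError(f"no NoiseSpec for state {s!r}")
            if self.noise[s].oscillation_freq >= self.sfreq / 2:
                raise ValueError("oscillation_freq must be below Nyquist")

    def times(self) -> np.ndarray:
        lo, hi = self.epoch_window
        n = int(round((hi - lo) * self.sfreq)) + 1
        return lo + np.arange(n) / self.sfreq


def generate_topography(
    layout: ChannelLayout, center: tuple[float, float], spread: float
) -> np.ndarray:
    """Gaussian spatial weight profile, renormalized to max 1.

    Weight falls off as exp(-d^2 / (2 spread^2)) with d the disc
    distance from ``center``; the channel nearest the center carries
    weight exactly 1.
    """
    if spread <= 0:
        raise ValueError("spread must be > 0")
    if layout.n_channels == 0:  # pragma: no cover - layout forbids this
        raise ValueError("layout has no channels")
    d = np.linalg.norm(layout.positions - np.asarray(center, float), axis=1)
    w = np.exp(-0.5 * (d / spread) ** 2)
    return w / w.max()


def generate_effect_timecourse(times: np.ndarray, spec: EffectSpec) -> np.ndarray:
    """Smooth biphasic evoked envelope on the given time grid.

    Zero before stimulus onset, positive lobe with its maximum at the
    middle of ``spec.peak_window``, a single sign change at
    ``spec.reversal_time``, then a negative lobe recovering toward zero
    at the epoch end.  Peak magnitude is 1; the planted signal is this
    envelope times the effect amplitude.  Built from a monotone
    piecewise-cubic (PCHIP) through shape-defining knots, so no segment
    overshoots and the zero crossing is unique.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be a sorted 1-D grid")
    t0, t_end = times[0], times[-1]
    if not (t0 <= spec.reversal_time <= t_end):
        raise ValueError("reversal_time lies outside the time grid")
    t_peak = 0.5 * (spec.peak_window[0] + spec.peak_window[1])
    if not (t0 <= spec.peak_window[0] and spec.peak_window[1] <= t_end):
        raise ValueError("peak_window lies outside the time grid")
    depth = 0.8  # negative lobe magnitude relative to the positive peak
    t_neg = min(spec.reversal_time + (spec.reversal_time - t_peak),
                0.5 * (spec.reversal_time + t_end))
    knots_t = [0.0, t_peak, spec.reversal_time, t_neg, t_end]
    knots_v = [0.0, 1.0, 0.0, -depth, -0.1 * depth]
    if t0 < 0.0:
        knots_t = [t0] + knots_t
        knots_v = [0.0] + knots_v
    if knots_t[-2] >= knots_t[-1]:  # reversal very close to epoch end
        knots_t = knots_t[:-1]
        knots_v = knots_v[:-1]
    env = PchipInterpolator(knots_t, knots_v)(times)
    env[times < 0.0] = 0.0
    peak = np.abs(env).max()
    if peak > 0:  # renormalize to the sampled grid (zeros/signs unchanged)
        env = env / peak
    return env


def _pink_noise(
    rng: np.random.Generator, shape: tuple[int, ...], exponent: float, sfreq: float
) -> np.ndarray:
    """1/f^alpha noise along the last axis, unit sample SD."""
    n_samp = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samp, 1.0 / sfreq)
    shaping = np.zeros_like(freqs)
    shaping[freqs > 0] = freqs[freqs > 0] ** (-exponent / 2.0)
    out = np.fft.irfft(spec * shaping, n=n_samp, axis=-1)
    sd = out.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def simulate_background(
    spec: NoiseSpec,
    n_trials: int,
    n_channels: int,
    times: np.ndarray,
    sfreq: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """State-specific background activity, trials x channels x samples, µV.

    Channels are independent (no spatial mixing); each trial-channel
    gets pink noise, a random-phase sinusoid at the state's
    characteristic frequency, and white sensor noise.
    """
    shape = (n_trials, n_channels, times.size)
    out = np.zeros(shape)
    if spec.pink_sd > 0:
        out += spec.pink_sd * _pink_noise(rng, shape, spec.pink_exponent, sfreq)
    if spec.oscillation_amp > 0 and spec.oscillation_freq > 0:
        phase = rng.uniform(0, 2 * np.pi, size=(n_trials, n_channels, 1))
        out += spec.oscillation_amp * np.sin(
            2 * np.pi * spec.oscillation_freq * times[None, None, :] + phase
        )
    if spec.white_sd > 0:
        out += spec.white_sd * rng.standard_normal(shape)
    return out


def _subject_effect(
    config: SimulationConfig, subject: int, contrast: str
) -> tuple[np.ndarray, float, EffectSpec]:
    """Per-subject jittered topography and amplitude for one contrast.

    Amplitude jitter is log-normal (multiplicative), topography-center
    jitter is Gaussian with SD = subject_variability * spread; both are
    functions of (seed, subject, contrast) only, so a subject carries
    the same idiosyncratic pattern in every state.
    """
    spec = config.effects[contrast]
    ss = np.random.SeedSequence(
        entropy=config.seed, spawn_key=(101, subject, CONTRASTS.index(contrast))
    )
    rng = np.random.default_rng(ss)
    sv = config.subject_variability
    amp = spec.amplitude * rng.lognormal(mean=0.0, sigma=sv)
    center = np.asarray(spec.topography_center, float) + rng.normal(
        0.0, sv * spec.topography_spread, size=2
    )
    # keep the jittered center on the head
    norm = np.linalg.norm(center)
    if norm > 0.95:
        center = center * (0.95 / norm)
    topo = generate_topography(config.layout, tuple(center), spec.topography_spread)
    return topo, amp, spec


def simulate_epochs(
    config: SimulationConfig, subject: int, state: str, contrast: str
) -> EpochSet:
    """Simulate one subject-state-contrast block of epochs.

    Returns balanced labels (first all 0, then all 1).  The planted
    class difference (topography x envelope x amplitude x subject
    jitter) is added to the deviant class (label 1) when ``state`` is in
    the effect's ``shared_states``; otherwise the two classes differ
    only by noise.  Output is fully determined by
    (config.seed, subject, state, contrast).
    """
    if state not in config.states:
        raise ValueError(f"unknown state {state!r}")
    if contrast not in config.effects:
        raise ValueError(f"unknown contrast {contrast!r}")
    if not 0 <= subject < config.n_subjects:
        raise ValueError("subject index out of range")
    times = config.times()
    n_per = config.n_epochs_per_condition[state]
    n_trials = 2 * n_per
    noise_rng = np.random.default_rng(
        np.random.SeedSequence(
            entropy=config.seed,
            spawn_key=(
                202,
                subject,
                config.states.index(state),
                CONTRASTS.index(contrast),
            ),
        )
    )
    data = simulate_background(
        config.noise[state], n_trials, config.layout.n_channels, times,
        config.sfreq, noise_rng,
    )
    labels = np.repeat([0, 1], n_per)
    topo, amp, spec = _subject_effect(config, subject, contrast)
    if state in spec.shared_states and amp > 0:
        env = generate_effect_timecourse(times, spec)
        signal = spec.sign * amp * np.outer(topo, env)  # channels x samples
        data[labels == 1] += signal[None, :, :]
    return EpochSet(
        data=data,
        times=times,
        labels=labels,
        state=state,
        subject=subject,
        sfreq=config.sfreq,
        layout=config.layout,
        contrast=contrast,
        log=[f"simulate(seed={config.seed}, subject={subject}, state={state}, "
             f"contrast={contrast})"],
    )
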