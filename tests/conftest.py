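import numpy as np
import pytest

from vigildecode import ChannelLayout, EpochSet


@pytest.fixture
def layout8() -> ChannelLayout:
    return ChannelLayout.default(8)


@pytest.fixture
def toy_epochs(layout8):
    """Factory for small EpochSets with pure-noise data at 250 Hz."""

    def make(
        n_trials=20, n_samples=64, sfreq=250.0, seed=0, t0=-0.2,
        labels=None, state="N2", layout=layout8, data=None,
    ) -> EpochSet:
        rng = np.random.default_rng(seed)
        if data is None:
            data = rng.standard_normal((n_trials, layout.n_channels, n_samples))
        if labels is None:
            labels = np.arange(n_trials) % 2
        times = t0 + np.arange(n_samples) / sfreq
        return EpochSet(
            data=data, times=times, labels=labels, state=state,
            subject=0, sfreq=sfreq, layout=layout, contrast="VOICE",
        )

    return make
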