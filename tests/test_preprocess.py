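"""Trial conditioning: filters, crop/decimate arithmetic,
standardization round-trip, balanced subsampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vigildecode import (
    PreprocessingParams,
    balance_epochs,
    bandpass_filter,
    crop,
    decimate,
    lowpass_filter,
    preprocess,
    standardize_trials,
    unstandardize_trials,
)


def sinusoid_epochs(make, freq, sfreq=250.0, n_samples=1251, amp=1.0, offset=0.0):
    t = -2.0 + np.arange(n_samples) / sfreq
    wave = amp * np.sin(2 * np.pi * freq * t) + offset
    data = np.tile(wave, (4, 8, 1))
    return make(n_trials=4, n_samples=n_samples, sfreq=sfreq, t0=-2.0, data=data)


class TestBandpass:
    def test_passband_amplitude_preserved(self, toy_epochs):
        ep = sinusoid_epochs(toy_epochs, freq=10.0)
        out = bandpass_filter(ep, 1.0, 20.0)
        mid = slice(300, 950)  # away from edge transients
        ratio = np.abs(out.data[0, 0, mid]).max() / np.abs(ep.data[0, 0, mid]).max()
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_stopband_attenuation_at_40hz(self, toy_epochs):
        ep = sinusoid_epochs(toy_epochs, freq=40.0)
        out = bandpass_filter(ep, 1.0, 20.0)
        mid = slice(300, 950)
        atten = np.abs(out.data[0, 0, mid]).max() / np.abs(ep.data[0, 0, mid]).max()
        assert 20 * np.log10(atten) < -20.0

    def test_dc_offset_removed(self, toy_epochs):
        ep = sinusoid_epochs(toy_epochs, freq=0.0, amp=0.0, offset=5.0)
        out = bandpass_filter(ep, 1.0, 20.0)
        assert np.abs(out.data[:, :, 300:950]).max() < 0.1

    def test_invalid_band_rejected(self, toy_epochs):
        ep = toy_epochs()
        with pytest.raises(ValueError):
            bandpass_filter(ep, 20.0, 1.0)
        with pytest.raises(ValueError):
            bandpass_filter(ep, 1.0, 200.0)


class TestCropDecimate:
    def test_crop_sample_count_matches_grid_enumeration(self, toy_epochs):
        ep = toy_epochs(n_samples=1251, t0=-2.0, sfreq=250.0)
        out = crop(ep, (-0.2, 1.0))
        # brute-force count of grid points in the closed interval
        expected = sum(1 for t in ep.times if -0.2 - 1e-9 <= t <= 1.0 + 1e-9)
        assert out.n_samples == expected == 301
        assert out.times[0] == pytest.approx(-0.2)
        assert out.times[-1] == pytest.approx(1.0)

    def test_crop_to_full_extent_is_identity(self, toy_epochs):
        ep = toy_epochs()
        out = crop(ep, (ep.times[0], ep.times[-1]))
        np.testing.assert_array_equal(out.data, ep.data)

    def test_empty_crop_rejected(self, toy_epochs):
        ep = toy_epochs(sfreq=250.0, t0=-0.2)
        with pytest.raises(ValueError):
            crop(ep, (10.0, 10.001))

    def test_decimate_sample_count_and_rate(self, toy_epochs):
        ep = toy_epochs(n_samples=301, sfreq=250.0)
        out = decimate(ep, 4)
        assert out.n_samples == int(np.ceil(301 / 4)) == 76
        assert out.sfreq == 62.5
        np.testing.assert_array_equal(out.times, ep.times[::4])

    def test_decimate_identity_and_composition(self, toy_epochs):
        ep = toy_epochs(n_samples=64)
        np.testing.assert_array_equal(decimate(ep, 1).data, ep.data)
        a = decimate(decimate(ep, 2), 2)
        b = decimate(ep, 4)
        np.testing.assert_array_equal(a.data, b.data)
        assert a.sfreq == b.sfreq

    def test_bad_factor_rejected(self, toy_epochs):
        with pytest.raises(ValueError):
            decimate(toy_epochs(), 0)


class TestStandardize:
    def test_hand_computed_two_sample_trial(self, toy_epochs):
        data = np.zeros((1, 8, 2))
        data[0, :, 0], data[0, :, 1] = 1.0, 3.0
        ep = toy_epochs(n_trials=1, n_samples=2, data=data, labels=np.array([0]))
        out = standardize_trials(ep)
        np.testing.assert_allclose(out.data[0, 0], [-1.0, 1.0])
        assert out.standardization.means[0, 0] == pytest.approx(2.0)
        assert out.standardization.scales[0, 0] == pytest.approx(1.0)  # population SD

    def test_idempotent_up_to_tolerance(self, toy_epochs):
        ep = standardize_trials(toy_epochs(seed=3))
        again = standardize_trials(ep)
        np.testing.assert_allclose(again.data, ep.data, atol=1e-12)

    def test_constant_channel_flagged_and_zeroed(self, toy_epochs):
        ep = toy_epochs(seed=1)
        ep.data[2, 5, :] = 42.0
        out = standardize_trials(ep)
        assert np.all(out.data[2, 5] == 0.0)
        assert out.standardization.flagged[2, 5]
        assert out.standardization.flagged.sum() == 1

    def test_round_trip_reconstructs_input(self, toy_epochs):
        ep = toy_epochs(seed=5)
        back = unstandardize_trials(standardize_trials(ep))
        np.testing.assert_allclose(back.data, ep.data, rtol=1e-10, atol=1e-12)

    def test_missing_record_rejected(self, toy_epochs):
        with pytest.raises(ValueError):
            unstandardize_trials(toy_epochs())


class TestBalance:
    def make_unbalanced(self, make, n0, n1):
        labels = np.r_[np.zeros(n0, int), np.ones(n1, int)]
        return make(n_trials=n0 + n1, labels=labels, seed=2)

    def test_caps_at_requested_count(self, toy_epochs):
        ep = self.make_unbalanced(toy_epochs, 120, 130)
        out = balance_epochs(ep, 100, seed=0)
        assert (out.labels == 0).sum() == (out.labels == 1).sum() == 100

    def test_short_condition_caps_both_classes(self, toy_epochs):
        # the N1-style branch: fewer available than requested
        ep = self.make_unbalanced(toy_epochs, 40, 55)
        out = balance_epochs(ep, 100, seed=0)
        assert (out.labels == 0).sum() == (out.labels == 1).sum() == 40

    def test_seeded_determinism(self, toy_epochs):
        ep = self.make_unbalanced(toy_epochs, 30, 50)
        a = balance_epochs(ep, 20, seed=9)
        b = balance_epochs(ep, 20, seed=9)
        np.testing.assert_array_equal(a.data, b.data)
        c = balance_epochs(ep, 20, seed=10)
        assert not np.array_equal(a.data, c.data)

    def test_empty_condition_rejected(self, toy_epochs):
        ep = toy_epochs(labels=np.zeros(20, int))
        with pytest.raises(ValueError):
            balance_epochs(ep, 10, seed=0)

    @pytest.mark.parametrize("n0,n1,n", [(11, 17, 8), (5, 5, 100), (60, 3, 10)])
    def test_exact_fifty_fifty_proportions(self, toy_epochs, n0, n1, n):
        ep = self.make_unbalanced(toy_epochs, n0, n1)
        out = balance_epochs(ep, n, seed=1)
        assert (out.labels == 0).sum() == (out.labels == 1).sum()
        assert out.n_trials == 2 * min(n, n0, n1)

    @given(n0=st.integers(1, 25), n1=st.integers(1, 25),
           n=st.integers(2, 40), seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_balance_always_exact_and_without_replacement(self, n0, n1, n, seed):
        from vigildecode import ChannelLayout, EpochSet

        labels = np.r_[np.zeros(n0, int), np.ones(n1, int)]
        data = np.arange(n0 + n1, dtype=float)[:, None, None] * np.ones((1, 2, 4))
        ep = EpochSet(
            data=data, times=np.arange(4) / 250.0, labels=labels,
            state="N2", subject=0, sfreq=250.0, layout=ChannelLayout.default(2),
        )
        out = balance_epochs(ep, n, seed=seed)
        k = min(n, n0, n1)
        assert (out.labels == 0).sum() == (out.labels == 1).sum() == k
        # without replacement: every kept trial is a distinct original
        assert len(np.unique(out.data[:, 0, 0])) == out.n_trials


class TestPipelineOrder:
    def test_stage_order_is_logged(self, toy_epochs):
        ep = toy_epochs(n_trials=24, n_samples=1251, t0=-2.0, sfreq=250.0)
        out = preprocess(ep, PreprocessingParams(n_balance=10))
        steps = [s.split("(")[0] for s in out.log]
        assert steps == ["bandpass", "crop", "decimate", "balance"]

    def test_lowpass_requires_valid_edge(self, toy_epochs):
        ep = toy_epochs(sfreq=62.5)
        with pytest.raises(ValueError):
            lowpass_filter(ep, 40.0)
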