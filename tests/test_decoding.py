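"""Per-timepoint classification and temporal generalization, including
the convex-optimizer oracle and the independent MNE cross-check."""

import numpy as np
import pytest
from scipy.optimize import minimize

from vigildecode import (
    ClassifierSpec,
    EffectSpec,
    ChannelLayout,
    SimulationConfig,
    cross_state_tgm,
    fit_decoder,
    fit_timepoint,
    peak_window_summary,
    prepare_for_decoding,
    simulate_epochs,
    temporal_generalization,
    within_state_tgm,
)
from vigildecode.decoding import TemporalGeneralizationMatrix
from vigildecode.preprocess import PreprocessingParams, preprocess
from vigildecode.simulate import default_noise_specs


def logreg_oracle(X, y, C=1.0):
    """Brute-force minimizer of the L2-penalized logistic loss
    0.5 ||w||^2 + C sum log(1 + exp(-y_i (w.x_i + b))), y in {-1,+1}."""
    ypm = 2.0 * np.asarray(y) - 1.0

    def loss(params):
        w, b = params[:-1], params[-1]
        z = ypm * (X @ w + b)
        return 0.5 * w @ w + C * np.logaddexp(0.0, -z).sum()

    res = minimize(loss, np.zeros(X.shape[1] + 1), method="BFGS",
                   options={"gtol": 1e-12, "maxiter": 10000})
    return res.x[:-1], res.x[-1]


class TestFitTimepoint:
    def test_matches_convex_optimizer_oracle(self):
        rng = np.random.default_rng(0)
        for trial in range(3):
            X = rng.standard_normal((12, 2 + trial))
            y = rng.permutation(np.arange(12) % 2)
            w, b = fit_timepoint(X, y, ClassifierSpec(tol=1e-10))
            w0, b0 = logreg_oracle(X, y)
            np.testing.assert_allclose(w, w0, atol=1e-6)
            assert b == pytest.approx(b0, abs=1e-6)

    def test_separable_toy_problem(self):
        X = np.r_[-np.ones((50, 1)), np.ones((50, 1))]
        y = np.r_[np.zeros(50, int), np.ones(50, int)]
        w, b = fit_timepoint(X, y)
        assert w[0] > 0
        pred = (X @ w + b >= 0).astype(int)
        assert (pred == y).mean() == 1.0

    def test_shuffled_labels_decode_at_chance(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((200, 5))
        y = rng.permutation(np.arange(200) % 2)
        w, b = fit_timepoint(X, y)
        X_new = rng.standard_normal((2000, 5))
        y_new = rng.integers(0, 2, 2000)
        acc = ((X_new @ w + b >= 0).astype(int) == y_new).mean()
        assert abs(acc - 0.5) < 0.05

    def test_single_class_rejected(self):
        X = np.zeros((10, 3))
        with pytest.raises(ValueError):
            fit_timepoint(X, np.zeros(10, int))


class TestTemporalGeneralization:
    def separable_epochs(self, make, n=20):
        # class signal only at sample 1 of 2; channel 0 carries it
        data = np.zeros((n, 8, 2))
        labels = np.arange(n) % 2
        data[:, 0, 1] = 2.0 * labels - 1.0
        data += 0.01 * np.random.default_rng(0).standard_normal(data.shape)
        return make(n_trials=n, n_samples=2, data=data, labels=labels)

    def test_two_by_two_matrix_matches_hand_applied_rule(self, toy_epochs):
        ep = self.separable_epochs(toy_epochs)
        dec = fit_decoder(ep)
        tgm = temporal_generalization(dec, ep)
        assert tgm.scores.shape == (2, 2)
        # hand-apply sign(w.x + b) per train/test time
        for i in range(2):
            for j in range(2):
                pred = (ep.data[:, :, j] @ dec.weights[i] + dec.intercepts[i] >= 0)
                acc = (pred.astype(int) == ep.labels).mean()
                assert tgm.scores[i, j] == acc
        # model trained at the informative time is perfect on it
        assert tgm.scores[1, 1] == 1.0

    def test_label_inversion_flips_scores(self, toy_epochs):
        ep = self.separable_epochs(toy_epochs)
        dec = fit_decoder(ep)
        flipped = ep.evolve(labels=1 - ep.labels)
        a = temporal_generalization(dec, ep).scores
        b = temporal_generalization(dec, flipped).scores
        np.testing.assert_allclose(a + b, 1.0)

    def test_channel_mismatch_rejected(self, toy_epochs):
        ep = self.separable_epochs(toy_epochs)
        dec = fit_decoder(ep)
        other = toy_epochs(layout=ChannelLayout.default(5), n_samples=2)
        with pytest.raises(ValueError):
            temporal_generalization(dec, other)

    def test_agrees_with_mne_generalizing_estimator(self, toy_epochs):
        """Independent cross-check: the same per-timepoint sklearn models
        applied by MNE's temporal-generalization machinery must produce
        the identical accuracy matrix."""
        from mne.decoding import GeneralizingEstimator
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(8)
        n, n_ch, n_t = 40, 6, 5
        data = rng.standard_normal((n, n_ch, n_t))
        labels = np.arange(n) % 2
        data[:, 0, :] += 1.5 * (2 * labels - 1)[:, None]
        train = toy_epochs(n_trials=n, n_samples=n_t,
                           layout=ChannelLayout.default(n_ch),
                           data=data, labels=labels)
        test_data = rng.standard_normal((n, n_ch, n_t))
        test_data[:, 0, :] += 1.5 * (2 * labels - 1)[:, None]
        test = toy_epochs(n_trials=n, n_samples=n_t,
                          layout=ChannelLayout.default(n_ch),
                          data=test_data, labels=labels)
        ours = temporal_generalization(fit_decoder(train), test).scores
        est = GeneralizingEstimator(
            LogisticRegression(C=1.0, solver="newton-cholesky",
                               max_iter=2000, tol=1e-8),
            scoring="accuracy", verbose="error",
        )
        est.fit(train.data, train.labels)
        theirs = est.score(test.data, test.labels)
        np.testing.assert_allclose(ours, theirs, atol=1e-12)


class TestWithinState:
    def null_epochs(self, make, n=40, n_samples=6):
        return make(n_trials=n, n_samples=n_samples, seed=13)

    def test_null_data_scores_near_chance(self, toy_epochs):
        ep = prepare_for_decoding(self.null_epochs(toy_epochs), lowpass=None)
        tgm = within_state_tgm(ep, seed=0)
        se = np.sqrt(0.25 / 20)  # 20 test trials per fold
        assert abs(tgm.scores.mean() - 0.5) < 3 * se

    def test_fold_split_reproducible(self, toy_epochs):
        ep = prepare_for_decoding(self.null_epochs(toy_epochs), lowpass=None)
        a = within_state_tgm(ep, seed=5)
        b = within_state_tgm(ep, seed=5)
        np.testing.assert_array_equal(a.scores, b.scores)
        assert a.n_folds == 2

    def test_planted_effect_peaks_in_window(self):
        cfg = SimulationConfig(
            n_subjects=2, states=("N2",), n_epochs_per_condition=60,
            layout=ChannelLayout.default(8),
            effects={"VOICE": EffectSpec(amplitude=40.0)}, seed=3,
        )
        ep = simulate_epochs(cfg, 0, "N2", "VOICE")
        ep = preprocess(ep, PreprocessingParams(n_balance=60))
        ep = prepare_for_decoding(ep)
        tgm = within_state_tgm(ep, seed=0)
        diag = np.diag(tgm.scores)
        in_win = (tgm.train_times >= 0.25) & (tgm.train_times <= 0.40)
        pre = tgm.train_times < 0.0
        assert diag[in_win].mean() > diag[pre].mean() + 0.1

    def test_too_few_trials_rejected(self, toy_epochs):
        ep = toy_epochs(n_trials=3, labels=np.array([0, 1, 1]))
        with pytest.raises(ValueError):
            within_state_tgm(ep)


class TestCrossState:
    def make_state_pair(self, shared, seed=0):
        """Two states; the second carries either the same or an
        orthogonal planted topography."""
        rng = np.random.default_rng(seed)
        n, n_ch, n_t = 60, 8, 5
        labels = np.arange(n) % 2
        topo_a = np.zeros(n_ch); topo_a[0] = 1.0
        topo_b = topo_a if shared else np.eye(n_ch)[4]
        out = []
        for state, topo in (("N2", topo_a), ("N3", topo_b)):
            data = rng.standard_normal((n, n_ch, n_t))
            data += 2.0 * (2 * labels - 1)[:, None, None] * topo[None, :, None]
            times = np.arange(n_t) / 250.0
            from vigildecode import EpochSet

            out.append(EpochSet(
                data=data, times=times, labels=labels, state=state,
                subject=0, sfreq=250.0, layout=ChannelLayout.default(n_ch),
            ))
        return out

    def test_shared_pattern_transfers_above_chance(self):
        train, test = self.make_state_pair(shared=True)
        tgm = cross_state_tgm(train, test)
        assert tgm.scores.mean() > 0.8
        assert tgm.train_state == "N2" and tgm.test_state == "N3"

    def test_orthogonal_pattern_does_not_transfer(self):
        train, test = self.make_state_pair(shared=False)
        tgm = cross_state_tgm(train, test)
        assert abs(tgm.scores.mean() - 0.5) < 0.1

    def test_same_state_rejected(self):
        train, test = self.make_state_pair(shared=True)
        with pytest.raises(ValueError):
            cross_state_tgm(train, train.evolve())


class TestPeakWindowSummary:
    def toy_tgm(self, scores):
        t = np.array([0.0, 0.1, 0.2])
        return TemporalGeneralizationMatrix(
            scores=scores, train_times=t, test_times=t,
            train_state="N2", test_state="N2", subject=0, n_folds=2,
        )

    def test_constant_matrix(self):
        tgm = self.toy_tgm(np.full((3, 3), 0.6))
        assert peak_window_summary(tgm, (0.0, 0.2)) == pytest.approx(0.6)

    def test_submatrix_mean_matches_enumeration(self):
        scores = np.arange(9).reshape(3, 3) / 10.0
        tgm = self.toy_tgm(scores)
        # window [0.1, 0.2] selects rows/cols 1..2 -> cells {4,5,7,8}/10
        assert peak_window_summary(tgm, (0.1, 0.2)) == pytest.approx(0.6)

    def test_empty_window_rejected(self):
        tgm = self.toy_tgm(np.full((3, 3), 0.5))
        with pytest.raises(ValueError):
            peak_window_summary(tgm, (5.0, 6.0))
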