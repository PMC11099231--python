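"""Sliding-window discriminator: Az scoring, LOO projections, permutation
thresholds, forward models, and planted-component recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from driftdecode.decode import (
    DiscriminatorResult,
    SlidingWindowConfig,
    az_score,
    component_amplitude_diff,
    forward_model,
    loo_discriminant,
    peak_latency,
    permutation_threshold,
    train_discriminator,
    window_centers,
    window_features,
)
from driftdecode.eeg_preprocess import EpochSet, default_montage
from driftdecode.synthetic_data import (
    ComponentSpec,
    DesignSpec,
    make_trial_schedule,
    simulate_epochs,
    simulate_null_epochs,
)


def _pair_count_auc(y, labels):
    """Brute-force AUC by counting concordant pairs (ties count 1/2)."""
    pos = y[labels == 1]
    neg = y[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (pos.size * neg.size)


def _labels_of(ep):
    return np.array([1 if l == "ND" else 0 for l in ep.labels])


def _planted_epochs(amplitude, seed, n_per_class=50, n_channels=32, both=False):
    rng = np.random.default_rng(1234)
    a = rng.standard_normal(n_channels)
    b = rng.standard_normal(n_channels)
    b -= a * (a @ b) / (a @ a)
    early = ComponentSpec((190.0, 370.0), a, amplitude=amplitude, noise_sd=1.0)
    late = ComponentSpec((520.0, 630.0), b, amplitude=amplitude if both else 0.0, noise_sd=1.0)
    design = DesignSpec(n_nd=n_per_class, n_ad=n_per_class, n_vd=1)
    sched = make_trial_schedule(design, "visual", seed=seed)
    sched = sched[sched["condition"].isin(["ND", "AD"])].reset_index(drop=True)
    assignment = {"AD": ("early", "late")} if both else {"AD": ("early",)}
    return simulate_epochs(sched, early, late, 250.0, seed=seed, assignment=assignment)


class TestAzScore:
    def test_worked_example(self):
        y = np.array([0.1, 0.4, 0.35, 0.8])
        labels = np.array([0, 0, 1, 1])
        assert az_score(y, labels) == pytest.approx(0.75)

    def test_all_ties_give_chance(self):
        assert az_score(np.ones(10), np.array([0, 1] * 5)) == pytest.approx(0.5)

    def test_perfect_ordering(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert az_score(y, np.array([0, 0, 1, 1])) == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            az_score(np.arange(4.0), np.zeros(4, dtype=int))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 40)
        y = rng.choice(np.linspace(-1, 1, 9), size=n)  # force some ties
        labels = np.zeros(n, dtype=int)
        labels[: n // 2] = 1
        rng.shuffle(labels)
        if labels.sum() in (0, n):
            return
        assert az_score(y, labels) == pytest.approx(_pair_count_auc(y, labels))


class TestTrainDiscriminator:
    def test_separable_data_classified_perfectly(self):
        X = np.vstack([np.full((10, 2), -2.0), np.full((10, 2), 2.0)])
        labels = np.array([0] * 10 + [1] * 10)
        w, b = train_discriminator(X, labels)
        pred = (X @ w + b) > 0
        assert np.array_equal(pred, labels.astype(bool))

    def test_heavy_regularization_shrinks_weights(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((40, 5))
        labels = rng.integers(0, 2, 40)
        w_small, _ = train_discriminator(X, labels, l2_lambda=1e-3)
        w_big, _ = train_discriminator(X, labels, l2_lambda=1e6)
        assert np.linalg.norm(w_big) < 1e-3 * max(np.linalg.norm(w_small), 1.0)

    def test_matches_sklearn_irls_solution(self):
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(3)
        X = rng.standard_normal((200, 2))
        labels = (X[:, 0] + 0.5 * rng.standard_normal(200) > 0).astype(int)
        lam = 1.0
        w, b = train_discriminator(X, labels, l2_lambda=lam)
        ref = LogisticRegression(C=1.0 / lam, tol=1e-12, max_iter=5000).fit(X, labels)
        np.testing.assert_allclose(w, ref.coef_[0], atol=1e-4)
        assert b == pytest.approx(ref.intercept_[0], abs=1e-4)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_discriminator(np.zeros((5, 2)), np.zeros(5, dtype=int))


class TestWindowFeatures:
    def _epochs(self, data, sfreq=250.0):
        n_tr, n_ch, n_sm = data.shape
        names, _ = default_montage(n_ch)
        times = np.arange(n_sm) * 1000.0 / sfreq
        return EpochSet(data, times, ["ND"] * n_tr, sfreq, names)

    def test_constant_epochs(self):
        ep = self._epochs(np.full((3, 2, 100), 4.2))
        F = window_features(ep, 100.0, SlidingWindowConfig())
        np.testing.assert_allclose(F, 4.2)

    def test_single_sample_window(self):
        data = np.arange(2 * 2 * 10, dtype=float).reshape(2, 2, 10)
        ep = self._epochs(data, sfreq=1000.0)
        cfg = SlidingWindowConfig(width_ms=1.0)
        F = window_features(ep, 3.0, cfg)
        np.testing.assert_allclose(F, data[:, :, 3])

    def test_hand_built_means(self):
        data = np.array(
            [[[1.0, 2.0, 3.0, 4.0], [10.0, 10.0, 20.0, 20.0]],
             [[0.0, 4.0, 4.0, 0.0], [-1.0, 1.0, -1.0, 1.0]]]
        )
        ep = self._epochs(data, sfreq=1000.0)
        cfg = SlidingWindowConfig(width_ms=4.0)
        F = window_features(ep, 2.0, cfg)  # samples at 0..3 ms
        np.testing.assert_allclose(F, [[2.5, 15.0], [2.0, 0.0]])

    def test_window_outside_epoch_rejected(self):
        ep = self._epochs(np.zeros((2, 2, 10)), sfreq=1000.0)
        with pytest.raises(ValueError):
            window_features(ep, 500.0, SlidingWindowConfig())


class TestLooDiscriminant:
    def test_default_grid_has_101_windows(self):
        assert window_centers(SlidingWindowConfig()).size == 101

    def test_planted_component_recovered(self):
        ep = _planted_epochs(amplitude=2.0, seed=11)
        res = loo_discriminant(ep, _labels_of(ep))
        assert res.az.max() > 0.9
        peak = res.window_centers_ms[int(res.az.argmax())]
        assert 180.0 <= peak <= 380.0  # inside the planted window +- one step

    def test_relabeling_flips_y_and_keeps_az(self):
        ep = simulate_null_epochs(30, 6, 250.0, seed=4)
        labels = _labels_of(ep)
        cfg = SlidingWindowConfig(center_start_ms=200.0, center_end_ms=260.0)
        res = loo_discriminant(ep, labels, cfg)
        res_flip = loo_discriminant(ep, 1 - labels, cfg)
        np.testing.assert_allclose(res_flip.y_out, -res.y_out, atol=1e-6)
        np.testing.assert_allclose(res_flip.az, res.az, atol=1e-12)

    def test_az_equals_pair_counting_on_every_window(self):
        ep = simulate_null_epochs(24, 4, 250.0, seed=8)
        labels = _labels_of(ep)
        cfg = SlidingWindowConfig(center_start_ms=0.0, center_end_ms=100.0)
        res = loo_discriminant(ep, labels, cfg)
        for j in range(res.az.size):
            assert res.az[j] == pytest.approx(_pair_count_auc(res.y_out[j], labels))

    def test_small_class_rejected(self):
        ep = simulate_null_epochs(12, 4, 250.0, seed=8)
        with pytest.raises(ValueError):
            loo_discriminant(ep, _labels_of(ep))

    def test_peak_az_monotone_in_amplitude(self):
        cfg = SlidingWindowConfig(center_start_ms=150.0, center_end_ms=450.0)
        means = []
        for amp in (0.0, 1.0, 2.0):
            peaks = [
                loo_discriminant(
                    _planted_epochs(amp, seed=30 + s, n_per_class=25, n_channels=8),
                    _labels_of(_planted_epochs(amp, seed=30 + s, n_per_class=25, n_channels=8)),
                    cfg,
                ).az.max()
                for s in range(4)
            ]
            means.append(np.mean(peaks))
        assert means[0] < means[1] < means[2]


class TestPermutationThreshold:
    def test_thresholds_above_chance(self):
        ep = simulate_null_epochs(40, 6, 250.0, seed=2)
        cfg = SlidingWindowConfig(center_start_ms=100.0, center_end_ms=200.0)
        thr = permutation_threshold(ep, _labels_of(ep), cfg, n_reps=100, seed=0, method="cv")
        assert np.all(thr > 0.5)

    def test_deterministic_under_seed(self):
        ep = simulate_null_epochs(40, 6, 250.0, seed=2)
        cfg = SlidingWindowConfig(center_start_ms=300.0, center_end_ms=300.0)
        t1 = permutation_threshold(ep, _labels_of(ep), cfg, n_reps=50, seed=5, method="loo")
        t2 = permutation_threshold(ep, _labels_of(ep), cfg, n_reps=50, seed=5, method="loo")
        np.testing.assert_array_equal(t1, t2)

    def test_few_reps_warn(self):
        ep = simulate_null_epochs(40, 6, 250.0, seed=2)
        cfg = SlidingWindowConfig(center_start_ms=300.0, center_end_ms=300.0)
        with pytest.warns(UserWarning):
            permutation_threshold(ep, _labels_of(ep), cfg, n_reps=10, seed=1, method="cv")


class TestForwardModel:
    def test_self_projection(self):
        y = np.array([1.0, -2.0, 0.5])
        np.testing.assert_allclose(forward_model(y[:, None], y), [1.0])

    def test_orthogonal_channel_zero(self):
        y = np.array([1.0, -1.0, 1.0, -1.0])
        x_orth = np.array([1.0, 1.0, 1.0, 1.0])
        X = np.stack([y, x_orth], axis=1)
        a = forward_model(X, y)
        assert a[0] == pytest.approx(1.0)
        assert a[1] == pytest.approx(0.0, abs=1e-12)

    def test_scaling_identity(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((20, 5))
        y = rng.standard_normal(20)
        np.testing.assert_allclose(
            forward_model(X, 3.0 * y), forward_model(X, y) / 3.0, rtol=1e-12
        )

    def test_zero_output_rejected(self):
        with pytest.raises(ValueError):
            forward_model(np.ones((3, 2)), np.zeros(3))


class TestPeakAndAmplitude:
    def _result(self, az, centers=None):
        n = az.size
        centers = centers if centers is not None else np.arange(n) * 10.0
        zeros = np.zeros((n, 2))
        return DiscriminatorResult(
            centers, zeros, np.zeros(n), np.zeros((n, 4)), az, zeros, np.array([0, 0, 1, 1])
        )

    def test_monotone_az_picks_last_point(self):
        res = self._result(np.linspace(0.5, 0.9, 6))
        assert peak_latency(res, (0.0, 50.0)) == 50.0

    def test_tie_breaks_to_earlier(self):
        res = self._result(np.array([0.5, 0.8, 0.8, 0.5]))
        assert peak_latency(res, (0.0, 30.0)) == 10.0

    def test_empty_window_rejected(self):
        res = self._result(np.array([0.5, 0.6]))
        with pytest.raises(ValueError):
            peak_latency(res, (100.0, 200.0))

    def test_planted_amplitude_difference_is_negative(self):
        ep = _planted_epochs(amplitude=2.0, seed=17)
        res = loo_discriminant(ep, _labels_of(ep))
        lat = peak_latency(res, (190.0, 370.0))
        assert component_amplitude_diff(res, lat) < 0.0

    def test_class_role_swap_antisymmetry(self):
        """Swapping which class counts as distractor negates the difference."""
        rng = np.random.default_rng(6)
        y = rng.standard_normal((3, 8))
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        res = self._swap_result(y, labels)
        swapped = self._swap_result(y, 1 - labels)
        d = component_amplitude_diff(res, 0.0)
        assert component_amplitude_diff(swapped, 0.0) == pytest.approx(-d)

    @staticmethod
    def _swap_result(y, labels):
        n = y.shape[0]
        centers = np.arange(n) * 10.0
        zeros = np.zeros((n, 2))
        return DiscriminatorResult(
            centers, zeros, np.zeros(n), y, np.full(n, 0.5), zeros, labels
        )

    def test_relabeled_training_leaves_difference_unchanged(self):
        """Retraining with flipped labels flips y as well, so the
        distractor-minus-ND amplitude difference is invariant."""
        ep = simulate_null_epochs(30, 6, 250.0, seed=6)
        labels = _labels_of(ep)
        cfg = SlidingWindowConfig(center_start_ms=200.0, center_end_ms=220.0)
        res = loo_discriminant(ep, labels, cfg)
        flip = loo_discriminant(ep, 1 - labels, cfg)
        d = component_amplitude_diff(res, 200.0)
        assert component_amplitude_diff(flip, 200.0) == pytest.approx(d, abs=1e-6)
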