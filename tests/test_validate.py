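"""Validation statistics: exact identities, the origin-slope oracle, and the
Monte-Carlo performance bounds."""

import numpy as np
import pytest

from qsarkit.errors import DegenerateResponseError, DomainError
from qsarkit.validate import (
    ObservedPredicted,
    cv_metrics,
    max_performance,
    min_performance,
    rmse,
    test_metrics as compute_test_metrics,
    tropsha_criteria,
)


def brute_force_rmse(y, y_hat):
    total = 0.0
    for a, b in zip(y, y_hat):
        total += (a - b) ** 2
    return (total / len(y)) ** 0.5


class TestCvMetrics:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        op = ObservedPredicted(y=y, y_hat=y.copy(), y_train_mean=2.5)
        q2, r = cv_metrics(op)
        assert q2 == 1.0 and r == 0.0

    def test_mean_prediction_gives_zero_q2(self):
        y = np.array([0.0, 1.0, 2.0, 3.0])
        op = ObservedPredicted(y=y, y_hat=np.full(4, y.mean()), y_train_mean=float(y.mean()))
        q2, _ = cv_metrics(op)
        assert q2 == pytest.approx(0.0, abs=1e-15)

    def test_rmse_forced_arithmetic(self):
        y = np.array([0.0, 1.0, 2.0, 3.0])
        y_hat = np.array([0.1, 0.9, 2.1, 2.9])
        _, r = cv_metrics(ObservedPredicted(y=y, y_hat=y_hat, y_train_mean=1.5))
        assert r == pytest.approx(0.1, abs=1e-15)

    def test_degenerate_response_rejected(self):
        op = ObservedPredicted(y=np.array([2.0, 2.0]), y_hat=np.array([1.0, 3.0]), y_train_mean=2.0)
        with pytest.raises(DegenerateResponseError):
            cv_metrics(op)

    def test_rmse_matches_brute_force_loop(self, rng):
        for _ in range(10):
            y = rng.normal(size=25)
            y_hat = y + rng.normal(0, 0.5, size=25)
            assert rmse(y, y_hat) == pytest.approx(brute_force_rmse(y, y_hat), abs=1e-12)


class TestTestMetrics:
    def test_perfect_prediction_identities(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        op = ObservedPredicted.from_training(y, y.copy(), y_train=y)  # same means
        rep = compute_test_metrics(op)
        assert rep.q2_1 == 1.0 and rep.q2_2 == 1.0 and rep.q2_3 == 1.0
        assert rep.rmse == 0.0 and rep.r_test == pytest.approx(1.0)
        assert rep.k_slope == 1.0 and rep.r2_0 == pytest.approx(1.0)

    def test_origin_slope_oracle(self):
        # k = sum(y*yhat)/sum(yhat^2) = (2+8+18)/(4+16+36) = 0.5
        op = ObservedPredicted(y=np.array([1.0, 2.0, 3.0]), y_hat=np.array([2.0, 4.0, 6.0]))
        rep = compute_test_metrics(op)
        assert rep.k_slope == pytest.approx(0.5, abs=1e-15)
        assert rep.r_test == pytest.approx(1.0)

    def test_q2_1_equals_q2_2_when_means_match(self, rng):
        y_train = np.array([0.0, 1.0, 2.0, 3.0, 4.0])  # mean 2
        y_test = np.array([1.0, 2.0, 3.0])  # mean 2 as well
        y_hat = y_test + rng.normal(0, 0.4, 3)
        rep = compute_test_metrics(ObservedPredicted.from_training(y_test, y_hat, y_train))
        assert rep.q2_1 == pytest.approx(rep.q2_2, abs=1e-14)

    def test_r_affine_invariant_rmse_not(self, rng):
        y = rng.normal(size=30)
        y_hat = y + rng.normal(0, 0.3, 30)
        rep1 = compute_test_metrics(ObservedPredicted(y=y, y_hat=y_hat))
        rep2 = compute_test_metrics(ObservedPredicted(y=y, y_hat=2.0 * y_hat + 1.0))
        assert rep1.r_test == pytest.approx(rep2.r_test, abs=1e-12)
        assert rep1.rmse != pytest.approx(rep2.rmse, abs=1e-6)

    def test_bounded_metrics(self, rng):
        for _ in range(20):
            y = rng.normal(size=15)
            y_hat = rng.normal(size=15)
            rep = compute_test_metrics(ObservedPredicted.from_training(y, y_hat, rng.normal(size=40)))
            assert rep.q2_2 <= 1.0 and rep.r2_0 <= 1.0
            assert -1.0 <= rep.r_test <= 1.0
            assert np.isfinite(rep.rmse) and rep.rmse >= 0

    def test_all_zero_predictions_rejected(self):
        op = ObservedPredicted(y=np.array([1.0, 2.0]), y_hat=np.array([0.0, 0.0]))
        with pytest.raises(DegenerateResponseError):
            compute_test_metrics(op)


class TestTropsha:
    def _report(self, y, y_hat, y_train):
        return compute_test_metrics(ObservedPredicted.from_training(y, y_hat, y_train))

    def test_perfect_model_passes_all(self, rng):
        y = rng.normal(size=20)
        rep = self._report(y, y.copy(), y)
        flags = tropsha_criteria(rep, q2_cv=0.9)
        assert all(flags.values())

    def test_halved_slope_fails_k(self):
        rep = compute_test_metrics(
            ObservedPredicted(y=np.array([1.0, 2.0, 3.0]), y_hat=np.array([2.0, 4.0, 6.0]))
        )
        flags = tropsha_criteria(rep, q2_cv=0.9)
        assert not flags["k_in_0.85_1.15"]

    def test_q2_boundary_is_strict(self, rng):
        y = rng.normal(size=20)
        rep = self._report(y, y.copy(), y)
        assert not tropsha_criteria(rep, q2_cv=0.5)["q2_cv_gt_0.5"]
        assert tropsha_criteria(rep, q2_cv=0.5000001)["q2_cv_gt_0.5"]


class TestPerformanceBounds:
    def test_zero_noise_max_is_degenerate_perfect(self):
        pool = np.linspace(0, 10, 100)
        b = max_performance(pool, noise_sd=0.0, n_test=30, n_reps=20, seed=3)
        assert np.all(b.distributions["rmse"] == 0.0)
        assert np.allclose(b.distributions["r"], 1.0)
        assert np.allclose(b.distributions["r2_0"], 1.0)

    def test_rmse_concentrates_on_noise_sd(self, rng):
        pool = rng.normal(5.0, 1.5, 400)
        sigma = 0.4
        b = max_performance(pool, noise_sd=sigma, n_test=200, n_reps=500, seed=11)
        vals = b.distributions["rmse"]
        mc_se = vals.std() / np.sqrt(len(vals))
        assert abs(vals.mean() - sigma) < 3 * mc_se + 0.003  # small bias of sqrt(mean)

    def test_min_performance_r_centred_on_zero(self, rng):
        pool = rng.normal(0.0, 2.0, 300)
        b = min_performance(pool, noise_sd=0.2, n_test=100, n_reps=400, seed=5)
        vals = b.distributions["r"]
        assert abs(vals.mean()) < 4 * vals.std() / np.sqrt(len(vals)) + 0.01

    def test_permutation_inflates_rmse(self, rng):
        pool = rng.normal(0.0, 2.0, 300)
        mx = max_performance(pool, noise_sd=0.2, n_test=100, n_reps=200, seed=5)
        mn = min_performance(pool, noise_sd=0.2, n_test=100, n_reps=200, seed=5)
        assert mn.distributions["rmse"].mean() > mx.distributions["rmse"].mean()

    def test_fixed_seed_reproducible(self):
        pool = np.linspace(0, 1, 50)
        a = max_performance(pool, 0.1, 20, 30, seed=7)
        b = max_performance(pool, 0.1, 20, 30, seed=7)
        for m in a.distributions:
            assert np.array_equal(a.distributions[m], b.distributions[m])

    def test_bad_arguments_rejected(self):
        with pytest.raises(DomainError):
            max_performance(np.arange(10.0), 0.1, 5, n_reps=0)
        with pytest.raises(DomainError):
            min_performance(np.arange(10.0), -0.1, 5)
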