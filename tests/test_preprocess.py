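"""Preprocessing filters and the fit/replay contract."""

import numpy as np
import pandas as pd
import pytest

from qsarkit.errors import DataValidationError
from qsarkit.preprocess import (
    apply_preprocess,
    center_scale,
    fit_preprocess,
    impute_features,
    preprocessing_report,
    remove_highly_correlated,
    remove_near_zero_variance,
)


class TestImpute:
    def test_mean_imputation(self):
        X = pd.DataFrame({"a": [1.0, np.nan, 3.0]})
        out, means = impute_features(X)
        assert list(out["a"]) == [1.0, 2.0, 3.0]
        assert means == {"a": 2.0}

    def test_no_missing_is_identity_but_records_means(self):
        X = pd.DataFrame({"a": [1.0, 3.0]})
        out, means = impute_features(X)
        pd.testing.assert_frame_equal(out, X)
        assert means["a"] == 2.0

    def test_single_observed_value_fills_all(self):
        X = pd.DataFrame({"a": [5.0, np.nan, np.nan]})
        out, _ = impute_features(X)
        assert list(out["a"]) == [5.0, 5.0, 5.0]

    def test_all_missing_column_named_in_error(self):
        X = pd.DataFrame({"good": [1.0, 2.0], "bad": [np.nan, np.nan]})
        with pytest.raises(DataValidationError, match="bad"):
            impute_features(X)


class TestNearZeroVariance:
    def test_constant_column_dropped(self):
        X = pd.DataFrame({"c": [7.0] * 20, "v": np.arange(20.0)})
        _, dropped = remove_near_zero_variance(X)
        assert dropped == ["c"]

    def test_31_to_1_dropped_30_to_1_kept(self):
        x31 = pd.DataFrame({"a": [0.0] * 31 + [1.0]})  # ratio 31, 6.25% unique
        _, dropped = remove_near_zero_variance(x31, freq_cut=30)
        assert dropped == ["a"]
        x30 = pd.DataFrame({"a": [0.0] * 30 + [1.0]})  # ratio exactly 30: kept
        _, dropped = remove_near_zero_variance(x30, freq_cut=30)
        assert dropped == []

    def test_unique_cut_protects_continuous_columns(self):
        # high freq ratio but many distinct values -> kept
        col = list(np.linspace(0, 1, 50)) + [0.5] * 50
        X = pd.DataFrame({"a": col})
        _, dropped = remove_near_zero_variance(X, freq_cut=30, unique_cut=10)
        assert dropped == []


class TestCorrelationFilter:
    def test_exact_duplicate_pair_drops_one(self):
        a = np.arange(10.0)
        X = pd.DataFrame({"a": a, "b": 2 * a})
        out, dropped = remove_highly_correlated(X)
        assert dropped == ["b"]  # tie on mean |r| -> larger index dropped
        assert list(out.columns) == ["a"]

    def test_uncorrelated_columns_untouched(self, random_matrix):
        out, dropped = remove_highly_correlated(random_matrix, cutoff=0.95)
        assert dropped == []

    def test_three_identical_columns_drop_two(self):
        a = np.arange(12.0)
        X = pd.DataFrame({"a": a, "b": a.copy(), "c": a.copy()})
        out, dropped = remove_highly_correlated(X)
        assert len(dropped) == 2 and list(out.columns) == ["a"]

    def test_final_matrix_below_cutoff_on_random_data(self, rng):
        base = rng.normal(size=(80, 6))
        # plant correlated copies
        X = np.column_stack([base, base[:, 0] + rng.normal(0, 0.05, 80), base[:, 2] * 1.01])
        df = pd.DataFrame(X, columns=[f"c{j}" for j in range(8)])
        out, _ = remove_highly_correlated(df, cutoff=0.95)
        corr = out.corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        assert corr.max() <= 0.95

    def test_zero_variance_column_rejected(self):
        X = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(DataValidationError):
            remove_highly_correlated(X)


class TestCenterScale:
    def test_two_point_column(self):
        X = pd.DataFrame({"a": [0.0, 2.0]})
        out, centers, scales = center_scale(X)
        assert out["a"].tolist() == pytest.approx([-0.7071067811865475, 0.7071067811865475])
        assert centers["a"] == 1.0 and scales["a"] == pytest.approx(np.sqrt(2))

    def test_post_conditions_on_random_matrix(self, random_matrix):
        out, _, _ = center_scale(random_matrix)
        assert np.all(np.abs(out.mean()) < 1e-10)
        assert np.all(np.abs(out.std(ddof=1) - 1) < 1e-10)

    def test_idempotent_within_tolerance(self, random_matrix):
        once, _, _ = center_scale(random_matrix)
        twice, _, _ = center_scale(once)
        assert np.allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)

    def test_constant_column_rejected(self):
        with pytest.raises(DataValidationError):
            center_scale(pd.DataFrame({"a": [3.0, 3.0]}))


class TestFitReplay:
    def _training_matrix(self, rng):
        X = pd.DataFrame(
            {
                "x1": rng.normal(size=40),
                "x2": rng.normal(size=40),
                "const": np.ones(40),
                "dup": np.zeros(40),
            }
        )
        X.loc[3, "x1"] = np.nan
        X["dup"] = X["x2"] * 3.0
        return X

    def test_replay_on_training_data_is_bit_identical(self, rng):
        X = self._training_matrix(rng)
        fitted, state = fit_preprocess(X)
        replayed = apply_preprocess(state, X)
        pd.testing.assert_frame_equal(fitted, replayed)
        assert np.array_equal(
            fitted.to_numpy(), replayed.to_numpy()
        )  # bitwise, not approximate

    def test_surviving_columns_consistent(self, rng):
        X = self._training_matrix(rng)
        fitted, state = fit_preprocess(X)
        assert list(fitted.columns) == state.surviving_columns
        assert "const" in state.dropped_nzv and "dup" in state.dropped_corr

    def test_new_row_at_training_means_maps_to_zero(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 3)), columns=["a", "b", "c"])
        _, state = fit_preprocess(X)
        new = pd.DataFrame([{c: state.centers[c] for c in state.surviving_columns}])
        for c in set(X.columns) - set(state.surviving_columns):
            new[c] = 0.0
        out = apply_preprocess(state, new)
        assert np.allclose(out.to_numpy(), 0.0, atol=1e-12)

    def test_missing_value_in_new_data_uses_training_mean(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
        _, state = fit_preprocess(X)
        new = pd.DataFrame({"a": [np.nan], "b": [1.0]})
        out = apply_preprocess(state, new)
        # imputed with training mean -> centred value 0
        assert out["a"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_missing_expected_column_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
        _, state = fit_preprocess(X)
        with pytest.raises(DataValidationError):
            apply_preprocess(state, pd.DataFrame({"a": [1.0]}))

    def test_extra_columns_warn_and_are_ignored(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
        fitted, state = fit_preprocess(X)
        new = X.copy()
        new["extra"] = 1.0
        with pytest.warns(UserWarning):
            out = apply_preprocess(state, new)
        pd.testing.assert_frame_equal(out, fitted)

    def test_state_json_round_trip(self, rng):
        from qsarkit.preprocess import PreprocessState

        X = self._training_matrix(rng)
        fitted, state = fit_preprocess(X)
        state2 = PreprocessState.from_json(state.to_json())
        pd.testing.assert_frame_equal(apply_preprocess(state2, X), fitted)

    def test_report_lists_drops_with_reasons(self, rng):
        X = self._training_matrix(rng)
        _, state = fit_preprocess(X)
        rep = preprocessing_report(state)
        assert set(rep["reason"]) == {"near_zero_variance", "high_correlation"}
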