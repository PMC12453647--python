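"""Imputation, scaling, encoding, outlier handling, and the fitted pipeline."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sepsisnet.cohort import Cohort, PatientRecord
from sepsisnet.errors import EncodingError, ImputationError
from sepsisnet.preprocessing import (
    FittedPreprocessor,
    PreprocessConfig,
    fit,
    impute_mean,
    impute_time_series,
    label_encode,
    minmax_scale,
    one_hot_encode,
    outlier_transform,
    transform,
    zscore_standardize,
)
from sepsisnet.simulate import SimConfig, simulate_cohort


class TestImputeMean:
    def test_missing_takes_observed_mean(self):
        out = impute_mean([1.0, -1.0, 3.0], [True, False, True])
        np.testing.assert_allclose(out, [1.0, 2.0, 3.0])

    def test_fully_observed_is_identity(self):
        out = impute_mean([1.0, 5.0], [True, True])
        np.testing.assert_array_equal(out, [1.0, 5.0])

    def test_all_missing_raises_naming_feature(self):
        with pytest.raises(ImputationError, match="Lactate"):
            impute_mean([0.0, 0.0], [False, False], "Lactate")


class TestImputeTimeSeries:
    @pytest.mark.parametrize(
        "values, mask, expected",
        [
            # interior/trailing gaps carry the previous value forward
            ([5, 0, 0, 7], [1, 0, 0, 1], [5, 5, 5, 7]),
            # leading gap takes the next observed value
            ([0, 4], [0, 1], [4, 4]),
            ([1, 2, 3], [1, 1, 1], [1, 2, 3]),
            ([0, 9, 0], [0, 1, 0], [9, 9, 9]),
        ],
    )
    def test_fill_rules(self, values, mask, expected):
        out = impute_time_series(np.array(values, float), np.array(mask, bool))
        np.testing.assert_array_equal(out, expected)

    def test_all_missing_raises(self):
        with pytest.raises(ImputationError):
            impute_time_series([0.0], [False])


class TestScaling:
    def test_minmax_endpoints(self):
        np.testing.assert_allclose(minmax_scale([0, 5, 10], 0, 10), [0, 0.5, 1])

    def test_minmax_constant_maps_to_zero(self):
        np.testing.assert_array_equal(minmax_scale([7, 7], 7, 7), [0, 0])

    def test_minmax_held_out_value_may_exceed_one(self):
        np.testing.assert_allclose(minmax_scale([12.0], 0, 10), [1.2])

    def test_zscore_population_oracle(self):
        # mu = 4, population sigma = sqrt(8/3)
        x = np.array([2.0, 4.0, 6.0])
        out = zscore_standardize(x, x.mean(), x.std())
        np.testing.assert_allclose(out, [-1.224744871, 0.0, 1.224744871])

    def test_zscore_already_standardized_unchanged(self):
        x = np.array([-1.0, 0.0, 1.0])
        out = zscore_standardize(x, 0.0, np.sqrt(2 / 3))
        np.testing.assert_allclose(out, x / np.sqrt(2 / 3), atol=1e-9)
        again = zscore_standardize(out, out.mean(), out.std())
        np.testing.assert_allclose(again, out, atol=1e-9)

    def test_zscore_constant_maps_to_zero(self):
        np.testing.assert_array_equal(zscore_standardize([3, 3], 3, 0), [0, 0])


class TestCategoricalEncoding:
    ORDER = ("Male", "Female", "Other")

    @pytest.mark.parametrize(
        "value, expected",
        [("Male", [1, 0, 0]), ("Female", [0, 1, 0]), ("Other", [0, 0, 1])],
    )
    def test_one_hot_follows_declared_order(self, value, expected):
        np.testing.assert_array_equal(one_hot_encode(value, self.ORDER), expected)

    def test_one_hot_unseen_strict_raises(self):
        with pytest.raises(EncodingError):
            one_hot_encode("Unknown", self.ORDER)

    def test_one_hot_unseen_lenient_all_zeros(self):
        np.testing.assert_array_equal(
            one_hot_encode("Unknown", self.ORDER, strict=False), [0, 0, 0]
        )

    @pytest.mark.parametrize("value, code", [("Male", 0), ("Female", 1), ("Other", 2)])
    def test_label_codes(self, value, code):
        assert label_encode(value, self.ORDER) == code

    def test_label_single_category_always_zero(self):
        assert label_encode("OnlyOne", ("OnlyOne", "X")) == 0

    def test_label_unseen_strict_raises(self):
        with pytest.raises(EncodingError):
            label_encode("Unknown", self.ORDER)


class TestOutlierTransform:
    def test_cap_replaces_with_threshold_values(self):
        out, flags = outlier_transform([0.0, 5.0, -4.0], 0.0, 1.0, 3.0, "cap")
        np.testing.assert_allclose(out, [0.0, 3.0, -3.0])
        np.testing.assert_array_equal(flags, [False, True, True])

    def test_within_threshold_identity(self):
        x = [1.0, -2.9, 2.9]
        out, flags = outlier_transform(x, 0.0, 1.0, 3.0, "cap")
        np.testing.assert_array_equal(out, x)
        assert not flags.any()

    def test_remove_marks_missing(self):
        out, flags = outlier_transform([5.0], 0.0, 1.0, 3.0, "remove")
        assert np.isnan(out[0]) and flags[0]

    def test_flag_leaves_values(self):
        out, flags = outlier_transform([5.0], 0.0, 1.0, 3.0, "flag")
        assert out[0] == 5.0 and flags[0]

    @given(
        st.lists(st.floats(-50, 50), min_size=2, max_size=30),
        st.floats(0.5, 5.0),
    )
    def test_capping_never_increases_abs_z(self, values, threshold):
        x = np.array(values)
        mu, sd = float(x.mean()), float(x.std())
        if sd == 0:
            return
        out, _ = outlier_transform(x, mu, sd, threshold, "cap")
        z_out = np.abs((out - mu) / sd)
        z_in = np.abs((x - mu) / sd)
        assert np.all(z_out <= z_in + 1e-9)
        assert z_out.max() <= threshold + 1e-9


def _shifted_cohorts(tiny_schema):
    """Train/val pair with a planted distribution shift in HR."""
    def rec(pid, hr_base, label=0):
        return PatientRecord(
            pid,
            [0, 1, 2],
            [[hr_base, 36.5, 7, 0], [hr_base + 1, 36.6, 8, 0], [hr_base + 2, 36.7, 9, 0]],
            np.ones((3, 4), bool),
            [label] * 3,
        )

    train = Cohort(tiny_schema, [rec("T1", 60), rec("T2", 80)])
    val = Cohort(tiny_schema, [rec("V1", 140)])
    return train, val


class TestFitTransform:
    def test_val_uses_train_statistics(self, tiny_schema):
        train, val = _shifted_cohorts(tiny_schema)
        fitted = fit(train, PreprocessConfig(outlier_policy="flag"))
        val_out = transform(val, fitted)
        j = val_out.feature_names.index("HR")
        # with train stats (mean ~71), HR=140-ish z-scores far above 0;
        # val's own stats would center its column at ~0
        assert val_out.patients[0].values[:, j].mean() > 3

    def test_transform_deterministic(self, small_sim_cohort):
        fitted = fit(small_sim_cohort)
        a = transform(small_sim_cohort, fitted)
        b = transform(small_sim_cohort, fitted)
        for pa, pb in zip(a.patients, b.patients):
            np.testing.assert_array_equal(pa.values, pb.values)

    def test_output_fully_observed_even_with_sparse_labs(self):
        cohort = simulate_cohort(
            SimConfig(n_patients=30, lab_missing_rate=0.9, seed=11)
        )
        fitted = fit(cohort)
        out = transform(cohort, fitted)
        for p in out.patients:
            assert np.isfinite(p.values).all()

    def test_training_split_moment_contract(self, small_sim_cohort):
        """Z-scored training output has mean 0 and sd 1 per numeric feature."""
        fitted = fit(small_sim_cohort)
        out = transform(small_sim_cohort, fitted)
        stacked = np.vstack([p.values for p in out.patients])
        for name in small_sim_cohort.schema.numeric_features():
            j = out.feature_names.index(name)
            col = stacked[:, j]
            if col.std() == 0:
                continue
            assert abs(col.mean()) < 1e-6
            assert abs(col.std() - 1.0) < 1e-6

    def test_minmax_training_range_contract(self, small_sim_cohort):
        fitted = fit(small_sim_cohort, PreprocessConfig(scaling="minmax"))
        out = transform(small_sim_cohort, fitted)
        stacked = np.vstack([p.values for p in out.patients])
        assert stacked.min() >= -1e-9 and stacked.max() <= 1 + 1e-9

    def test_refit_on_transformed_is_idempotent(self, small_sim_cohort):
        """Re-fitting on z-scored output yields mu ~ 0, sigma ~ 1."""
        fitted = fit(small_sim_cohort)
        out = transform(small_sim_cohort, fitted)
        stacked = np.vstack([p.values for p in out.patients])
        for name in small_sim_cohort.schema.numeric_features():
            j = out.feature_names.index(name)
            assert abs(stacked[:, j].mean()) < 1e-6
            assert abs(stacked[:, j].std() - 1) < 1e-6

    def test_one_hot_rows_sum_to_one(self, small_sim_cohort):
        fitted = fit(small_sim_cohort)
        out = transform(small_sim_cohort, fitted)
        cols = [i for i, n in enumerate(out.feature_names) if n.startswith("Gender=")]
        stacked = np.vstack([p.values for p in out.patients])
        np.testing.assert_array_equal(stacked[:, cols].sum(axis=1), 1.0)

    def test_remove_policy_reimputes(self, tiny_schema):
        rec = PatientRecord(
            "A",
            [0, 1, 2, 3, 4],
            [[80, 36.5, 7, 0], [81, 36.5, 7, 0], [82, 36.6, 7, 0],
             [500, 36.6, 7, 0], [83, 36.7, 7, 0]],
            np.ones((5, 4), bool),
            [0] * 5,
        )
        cohort = Cohort(tiny_schema, [rec])
        fitted = fit(cohort, PreprocessConfig(outlier_policy="remove",
                                              outlier_threshold=1.5))
        out = transform(cohort, fitted)
        assert np.isfinite(out.patients[0].values).all()

    def test_save_load_round_trip(self, small_sim_cohort, tmp_path):
        fitted = fit(small_sim_cohort)
        fitted.save(tmp_path / "pre.yaml")
        back = FittedPreprocessor.load(tmp_path / "pre.yaml", small_sim_cohort.schema)
        a = transform(small_sim_cohort, fitted)
        b = transform(small_sim_cohort, back)
        for pa, pb in zip(a.patients, b.patients):
            np.testing.assert_allclose(pa.values, pb.values, atol=1e-12)
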