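"""Preprocessing: imputation, encoding, scaling, SMOTE, leakage discipline."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gsoelm import (
    ColumnSpec, RawSchema, build_design_matrix, encode_boolean,
    fit_scaler, apply_scaler, impute_categorical_mode, impute_numeric_mean,
    one_hot_encode, smote_oversample, FeatureSchema,
)


def _series(values):
    return pd.Series(values, name="col")


class TestImputation:
    @pytest.mark.parametrize("values,expected", [
        ([1.0, 2.0, None, 3.0], [1.0, 2.0, 2.0, 3.0]),   # mean of {1,2,3}
        ([5.0, 5.0, 5.0], [5.0, 5.0, 5.0]),               # no missing: identity
    ])
    def test_numeric_mean(self, values, expected):
        out = impute_numeric_mean(_series(values), np.ones(len(values), bool))
        assert out.tolist() == expected

    def test_numeric_mean_uses_training_rows_only(self):
        col = _series([1.0, None, 100.0])
        out = impute_numeric_mean(col, np.array([True, True, False]))
        assert out.tolist() == [1.0, 1.0, 100.0]

    def test_numeric_all_missing_errors_with_column_name(self):
        with pytest.raises(ValueError, match="col"):
            impute_numeric_mean(_series([None, None]), np.ones(2, bool))

    @pytest.mark.parametrize("values,expected", [
        (["a", "a", "b", None], ["a", "a", "b", "a"]),     # mode a (2 > 1)
        (["x", None], ["x", "x"]),
        (["a", "b", None], ["a", "b", "a"]),               # tie -> lexicographic
    ])
    def test_categorical_mode(self, values, expected):
        out = impute_categorical_mode(_series(values), np.ones(len(values), bool))
        assert out.tolist() == expected

    def test_categorical_all_missing_errors(self):
        with pytest.raises(ValueError):
            impute_categorical_mode(_series([None, ""]), np.ones(2, bool))


class TestEncoding:
    @pytest.mark.parametrize("value,vocab,expected", [
        ("Male", ["Male", "Female"], [1, 0]),
        ("Female", ["Male", "Female"], [0, 1]),
        ("c", ["a", "b", "c", "d"], [0, 0, 1, 0]),
    ])
    def test_one_hot(self, value, vocab, expected):
        assert one_hot_encode(value, vocab).tolist() == expected

    def test_one_hot_unseen_strict_errors(self):
        with pytest.raises(ValueError, match="unseen"):
            one_hot_encode("e", ["a", "b"])

    def test_one_hot_unseen_lenient_all_zeros(self):
        assert one_hot_encode("e", ["a", "b"], strict=False).tolist() == [0, 0]

    @pytest.mark.parametrize("value,expected", [("Yes", 1), ("No", 0)])
    def test_boolean(self, value, expected):
        assert encode_boolean(value) == expected

    def test_boolean_outside_pair_errors(self):
        with pytest.raises(ValueError):
            encode_boolean("maybe")


class TestScaling:
    def test_minmax_fitted_values(self):
        df = pd.DataFrame({"age": [12.0, 28.0, 36.0]})
        spec = fit_scaler("minmax", df, np.ones(3, bool))
        out = apply_scaler(spec, df)["age"].to_numpy()
        assert out == pytest.approx([0.0, 16 / 24, 1.0])

    def test_minmax_known_bounds(self):
        df = pd.DataFrame({"q": [3.0, 9.0]})
        spec = fit_scaler("minmax", df, np.ones(2, bool), bounds={"q": (0, 10)})
        assert apply_scaler(spec, df)["q"].to_numpy() == pytest.approx([0.3, 0.9])

    def test_zscore_train_mean_zero_sd_one(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 10.0]})
        train = np.array([True, True, True, False])
        spec = fit_scaler("zscore", df, train)
        out = apply_scaler(spec, df)["x"].to_numpy()
        assert out[:3].mean() == pytest.approx(0.0)
        assert out[:3].std(ddof=0) == pytest.approx(1.0)

    def test_robust_train_median_zero(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0, 100.0]})
        spec = fit_scaler("robust", df, np.ones(5, bool))
        out = apply_scaler(spec, df)["x"].to_numpy()
        assert np.median(out) == pytest.approx(0.0)

    @pytest.mark.parametrize("kind", ["minmax", "zscore"])
    def test_constant_column_errors_naming_column(self, kind):
        df = pd.DataFrame({"flat": [2.0, 2.0, 2.0]})
        with pytest.raises(ValueError, match="flat"):
            fit_scaler(kind, df, np.ones(3, bool))

    def test_statistics_from_train_rows_only(self):
        df = pd.DataFrame({"x": [0.0, 10.0, 999.0]})
        train = np.array([True, True, False])
        spec = fit_scaler("minmax", df, train)
        out = apply_scaler(spec, df)["x"].to_numpy()
        assert out[:2].tolist() == [0.0, 1.0]
        assert out[2] > 1.0  # test rows may fall outside [0,1]; no clipping

    @given(st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=30, unique=True))
    @settings(deadline=None, max_examples=50)
    def test_minmax_train_rows_in_unit_interval(self, values):
        df = pd.DataFrame({"x": values})
        spec = fit_scaler("minmax", df, np.ones(len(values), bool))
        out = apply_scaler(spec, df)["x"].to_numpy()
        assert out.min() == pytest.approx(0.0, abs=1e-12)
        assert out.max() == pytest.approx(1.0, abs=1e-12)


class TestBuildDesignMatrix:
    def test_fixture_width_and_completeness(self, sample_table, toddler_schema):
        dm, fs = build_design_matrix(sample_table, toddler_schema)
        assert dm.X.shape == (20, 16)
        assert np.isfinite(dm.X).all()
        assert fs.n_features == 16

    def test_one_hot_blocks_row_sum_to_one(self, sample_table, toddler_schema):
        dm, fs = build_design_matrix(sample_table, toddler_schema)
        for name, cols in fs.groups.items():
            if len(cols) > 1:
                block = dm.X[:, cols]
                assert set(np.unique(block)) <= {0.0, 1.0}
                assert np.all(block.sum(axis=1) == 1.0)
                assert len(cols) == len(fs.vocabularies[name])

    def test_worked_row_age15_qchat7(self, sample_table, toddler_schema):
        # age 15, QCHAT 7, f, Middle Eastern, jaundice Yes, no family history
        dm, _ = build_design_matrix(sample_table, toddler_schema)
        expected = [0.125, 0.7, 1, 0, 0, 0, 0, 1, 0, 0, 0, 1, 1, 0, 1, 0]
        assert dm.X[13] == pytest.approx(expected, abs=5e-5)

    def test_single_numeric_column(self):
        schema = RawSchema([ColumnSpec("x", "numeric"), ColumnSpec("y", "label")])
        raw = pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": ["Yes", "No", "Yes"]})
        dm, fs = build_design_matrix(raw, schema)
        assert dm.X.shape == (3, 1)
        assert fs.n_features == 1

    def test_one_hot_columns_not_rescaled_under_zscore(self, sample_table, toddler_schema):
        dm, fs = build_design_matrix(sample_table, toddler_schema, scaler="zscore")
        onehot = [i for cols in fs.groups.values() if len(cols) > 1 for i in cols]
        assert set(np.unique(dm.X[:, onehot])) <= {0.0, 1.0}

    def test_unitnorm_rows_have_unit_length(self, sample_table, toddler_schema):
        dm, _ = build_design_matrix(sample_table, toddler_schema, scaler="unitnorm")
        assert np.linalg.norm(dm.X, axis=1) == pytest.approx(np.ones(20))

    def test_deterministic(self, sample_table, toddler_schema):
        a, _ = build_design_matrix(sample_table, toddler_schema)
        b, _ = build_design_matrix(sample_table, toddler_schema)
        np.testing.assert_array_equal(a.X, b.X)

    def test_changing_test_rows_leaves_fitted_statistics_alone(self, sample_table, toddler_schema):
        train = np.array([True] * 15 + [False] * 5)
        perturbed = sample_table.copy()
        perturbed.loc[17, "Age_Mons"] = 99
        perturbed.loc[18, "Qchat_10_Score"] = 3
        _, fs_a = build_design_matrix(sample_table, toddler_schema, train_mask=train)
        _, fs_b = build_design_matrix(perturbed, toddler_schema, train_mask=train)
        assert fs_a.scaler.shift == fs_b.scaler.shift
        assert fs_a.scaler.scale == fs_b.scaler.scale
        assert fs_a.numeric_means == fs_b.numeric_means

    def test_missing_cells_imputed_everywhere(self, toddler_schema):
        from gsoelm import GeneratorConfig, generate
        ds = generate(GeneratorConfig(n=80, missing_rate=0.2, seed=3))
        assert ds.table.isna().to_numpy().any()
        dm, _ = build_design_matrix(ds.table, toddler_schema)
        assert np.isfinite(dm.X).all()

    def test_schema_json_round_trip(self, sample_table, toddler_schema, tmp_path):
        dm, fs = build_design_matrix(sample_table, toddler_schema)
        path = tmp_path / "schema.json"
        fs.save(path)
        reloaded = FeatureSchema.load(path)
        X, y = reloaded.transform(sample_table)
        np.testing.assert_allclose(X, dm.X)
        np.testing.assert_array_equal(y, dm.y)


class TestSmote:
    def _data(self, n_pos, n_neg, seed=0):
        rng = np.random.default_rng(seed)
        X = np.vstack([rng.normal(2, 1, (n_pos, 3)), rng.normal(-2, 1, (n_neg, 3))])
        y = np.array([1] * n_pos + [0] * n_neg)
        return X, y

    def test_balances_classes(self):
        X, y = self._data(10, 40)
        X2, y2 = smote_oversample(X, y, seed=1)
        counts = np.bincount(y2)
        assert counts[0] == counts[1] == 40
        assert X2.shape[0] == 80

    def test_already_balanced_unchanged(self):
        X, y = self._data(20, 20)
        X2, y2 = smote_oversample(X, y, seed=1)
        np.testing.assert_array_equal(X2, X)
        np.testing.assert_array_equal(y2, y)

    def test_seeded_reproducibility(self):
        X, y = self._data(10, 30)
        a = smote_oversample(X, y, seed=7)[0]
        b = smote_oversample(X, y, seed=7)[0]
        np.testing.assert_array_equal(a, b)

    def test_synthetic_rows_interpolate_minority(self):
        X, y = self._data(8, 30)
        X2, y2 = smote_oversample(X, y, seed=2)
        synth = X2[len(X):]
        lo, hi = X[y == 1].min(axis=0), X[y == 1].max(axis=0)
        assert np.all(synth >= lo - 1e-9) and np.all(synth <= hi + 1e-9)

    def test_small_minority_reduces_k_with_warning(self, caplog):
        X, y = self._data(3, 20)
        with caplog.at_level("WARNING", logger="gsoelm.preprocessing"):
            X2, y2 = smote_oversample(X, y, k_neighbors=5, seed=1)
        assert "reducing k" in caplog.text
        assert np.bincount(y2)[1] == 20

    def test_single_class_errors(self):
        X = np.zeros((5, 2))
        with pytest.raises(ValueError, match="single-class"):
            smote_oversample(X, np.ones(5, dtype=int), seed=0)

    def test_one_hot_repair_with_schema(self, sample_table, toddler_schema):
        dm, fs = build_design_matrix(sample_table, toddler_schema)
        X2, y2 = smote_oversample(dm.X, dm.y, k_neighbors=3, seed=4, schema=fs)
        for name, cols in fs.groups.items():
            if len(cols) > 1:
                assert np.all(X2[:, cols].sum(axis=1) == 1.0)
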