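"""Preprocessing, feature reduction, model zoo, and error-band metrics."""

import numpy as np
import pandas as pd
import pytest

from nucleokin import (
    ModelSpec,
    constant_value_models,
    error_band_metrics,
    generate_hydrodynamic_features,
    pca_variance,
    preprocess,
    r2_with_nan,
    reduce_features,
    train_regressors,
    vessel_configs,
)
from nucleokin.ml_correlation import ErrorBand, build_feature_matrix


@pytest.fixture(scope="module")
def matrix():
    configs = vessel_configs()
    feats = generate_hydrodynamic_features(configs, seed=0)
    return build_feature_matrix(configs, feats.reset_index())


@pytest.fixture
def flat_band():
    return ErrorBand(mae_J_at_M={5: 0.1, 20: 0.05},
                     mae_tg_at_M={5: 300.0, 20: 100.0},
                     mae_log10_J_at_M={5: 0.3, 20: 0.1})


class TestPreprocess:
    def test_log_transform_and_training_standardization(self, matrix):
        y = pd.Series(1.0, index=matrix.index)  # J = 1 -> log10 J = 0
        out = preprocess(matrix, "J", y)
        assert (out["y_train"] == 0).all()
        numeric = [c for c in out["X_train"].columns
                   if not c.startswith("impeller_")]
        assert np.allclose(out["X_train"][numeric].mean(), 0, atol=1e-10)
        assert np.allclose(out["X_train"][numeric].var(ddof=0), 1, atol=1e-10)

    def test_onehot_encoding(self, matrix):
        out = preprocess(matrix, "t_g", pd.Series(1.0, index=matrix.index))
        rc_rows = matrix["impeller_type"] == "RC"
        assert (out["X_train"].loc[rc_rows[rc_rows].index.intersection(
            out["X_train"].index), "impeller_RC"] == 1).all()
        assert set(out["X_train"]["impeller_RC"] + out["X_train"]["impeller_PBT"]) == {1.0}

    def test_test_rows_use_training_statistics(self, matrix):
        y = pd.Series(np.arange(len(matrix), dtype=float) + 1, index=matrix.index)
        ref = preprocess(matrix, "t_g", y)
        mutated = matrix.copy()
        test_rows = mutated["split_label"] == "testing"
        mutated.loc[test_rows, "sr_mean"] *= 100.0  # must not touch the stats
        out = preprocess(mutated, "t_g", y)
        assert out["mean"].equals(ref["mean"]) and out["std"].equals(ref["std"])
        assert out["X_train"].equals(ref["X_train"])

    def test_nonpositive_J_rejected(self, matrix):
        y = pd.Series(1.0, index=matrix.index)
        y.iloc[0] = -2.0
        with pytest.raises(ValueError, match="positive"):
            preprocess(matrix, "J", y)

    def test_zero_variance_column_named(self, matrix):
        broken = matrix.copy()
        broken["sr_mean"] = 1.0
        with pytest.raises(ValueError, match="sr_mean"):
            preprocess(broken, "t_g", pd.Series(1.0, index=matrix.index))


class TestReduceFeatures:
    def _frame(self, data):
        df = pd.DataFrame(data)
        df["split_label"] = "training_validation"
        return df

    def test_duplicated_column_keeps_one(self, rng):
        x = rng.normal(size=50)
        df = self._frame({"a": x, "b": x, "c": rng.normal(size=50)})
        reduced, dropped = reduce_features(df, numeric_columns=("a", "b", "c"))
        assert dropped == ["b"]

    def test_independent_columns_all_survive(self, rng):
        df = self._frame({f"c{i}": rng.normal(size=200) for i in range(6)})
        _, dropped = reduce_features(df, numeric_columns=tuple(f"c{i}" for i in range(6)))
        assert dropped == []

    def test_three_latent_blocks_leave_three_survivors(self, rng):
        latents = rng.normal(size=(120, 3))
        cols = {}
        for b in range(3):
            for k in range(4):
                cols[f"b{b}_{k}"] = latents[:, b] * (1 + 0.1 * k) + \
                    1e-4 * rng.normal(size=120)
        df = self._frame(cols)
        names = tuple(cols)
        reduced, dropped = reduce_features(df, numeric_columns=names)
        kept = [c for c in reduced.columns if c in names]
        assert len(kept) == 3
        # brute-force oracle: surviving pairwise |r| all <= 0.95
        corr = np.corrcoef(df[kept].to_numpy(), rowvar=False)
        assert np.abs(corr[~np.eye(3, dtype=bool)]).max() <= 0.95


class TestPcaVariance:
    def test_fractions_sum_to_one_and_are_sorted(self, matrix):
        frac = pca_variance(matrix)
        assert frac.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(np.diff(frac) <= 1e-12)
        assert np.all(frac >= -1e-15)

    def test_rank_two_data(self, rng):
        a, b = rng.normal(size=(2, 100))
        df = pd.DataFrame({"x": a, "y": b, "z": a + b, "w": a - 2 * b})
        frac = pca_variance(df, numeric_columns=("x", "y", "z", "w"))
        assert np.all(frac[2:] < 1e-10)

    def test_isotropic_data_has_flat_spectrum(self, rng):
        p = 8
        df = pd.DataFrame(rng.normal(size=(4000, p)),
                          columns=[f"c{i}" for i in range(p)])
        frac = pca_variance(df, numeric_columns=tuple(df.columns))
        assert frac[0] < (2 / p) * 1.5


class TestModelZoo:
    def test_linear_model_recovers_exact_linear_target(self, matrix):
        y = 5000.0 + 3.0 * matrix["sr_mean"] - 0.5 * matrix["impeller_speed"]
        models = train_regressors(matrix, "t_g", y,
                                  [ModelSpec("lin", "linear")],
                                  feature_columns=("sr_mean", "impeller_speed"),
                                  seed=0)
        assert models["lin"].loo_rmse < 1e-6

    def test_constant_target_fits_perfectly_everywhere(self, matrix):
        y = pd.Series(7000.0, index=matrix.index)
        specs = [ModelSpec("lin", "linear"), ModelSpec("rf", "random_forest"),
                 ModelSpec("knn", "knn"),
                 ModelSpec("c", "constant", grouping="all")]
        models = train_regressors(matrix, "t_g", y, specs, seed=0)
        for m in models.values():
            assert m.loo_rmse < 1e-8

    def test_loo_fold_count_equals_training_rows(self, matrix):
        y = pd.Series(np.linspace(1000, 9000, len(matrix)), index=matrix.index)
        models = train_regressors(matrix, "t_g", y,
                                  [ModelSpec("knn", "knn")], seed=0)
        n_train = (matrix["split_label"] == "training_validation").sum()
        assert len(models["knn"].loo_predictions) == n_train == 14

    def test_unknown_model_and_feature_rejected(self, matrix):
        y = pd.Series(1.0, index=matrix.index)
        with pytest.raises(ValueError):
            ModelSpec("bad", "svm")
        with pytest.raises(ValueError, match="nonexistent"):
            train_regressors(matrix, "t_g", y,
                             [ModelSpec("u", "univariate", feature="nonexistent")])


class TestConstantValueModels:
    def test_grouped_means_recovered_exactly(self, matrix):
        y = pd.Series(np.where(matrix["impeller_type"] == "RC", 8000.0, 3000.0),
                      index=matrix.index)
        preds = constant_value_models(y, matrix, grouping="by_impeller_type")
        assert (preds[matrix["impeller_type"] == "RC"] == 8000.0).all()
        assert (preds[matrix["impeller_type"] == "PBT"] == 3000.0).all()

    def test_single_row_group_predicts_itself(self, matrix):
        sub = matrix.iloc[:4].copy()  # contains exactly one PBT training row?
        sub["split_label"] = "training_validation"
        sub.iloc[0, sub.columns.get_loc("impeller_type")] = "PBT"
        sub.iloc[1:, sub.columns.get_loc("impeller_type")] = "RC"
        y = pd.Series([1111.0, 2.0, 4.0, 6.0], index=sub.index)
        preds = constant_value_models(y, sub, grouping="by_impeller_type")
        assert preds.iloc[0] == 1111.0
        assert (preds.iloc[1:] == 4.0).all()

    def test_all_grouping_is_training_mean(self, matrix):
        y = pd.Series(np.arange(len(matrix), dtype=float), index=matrix.index)
        train = matrix["split_label"] == "training_validation"
        preds = constant_value_models(y, matrix, grouping="all")
        assert (preds == y[train].mean()).all()


class TestMetrics:
    def test_perfect_predictions_hit_both_bands(self, flat_band):
        ev = error_band_metrics([1.0, 2.0], [1.0, 2.0], flat_band, "t_g")
        assert (ev.pct_within_m5, ev.pct_within_m20) == (100.0, 100.0)
        assert ev.rmse == 0.0

    def test_zero_band_counts_only_exact_matches(self):
        band = ErrorBand({5: 0.0, 20: 0.0}, {5: 0.0, 20: 0.0}, {5: 0.0, 20: 0.0})
        ev = error_band_metrics([1.0, 2.0, 3.0], [1.0, 2.5, 3.5], band, "t_g")
        assert ev.pct_within_m5 == pytest.approx(100 / 3)

    def test_two_of_three_within_band(self):
        band = ErrorBand({5: 0.2, 20: 0.2}, {5: 0.2, 20: 0.2}, {5: 0.2, 20: 0.2})
        ev = error_band_metrics([0.1, 2.0, -1.05], [0.0, 1.0, -1.0], band, "t_g")
        assert ev.pct_within_m5 == pytest.approx(100 * 2 / 3, abs=0.05)

    def test_J_band_uses_log_scale_half_width(self, flat_band):
        # |pred - actual| = 0.2 on the log10 scale: inside M=5 (0.3), outside M=20 (0.1)
        ev = error_band_metrics([0.2], [0.0], flat_band, "J")
        assert (ev.pct_within_m5, ev.pct_within_m20) == (100.0, 0.0)

    @pytest.mark.parametrize("preds, actuals, expected", [
        ((1.0, 2.0, 3.0), (1.0, 2.0, 3.0), 1.0),
        ((2.0, 2.0, 2.0), (1.0, 2.0, 3.0), 0.0),  # predicting the mean
    ])
    def test_r2_examples(self, preds, actuals, expected):
        assert r2_with_nan(preds, actuals) == pytest.approx(expected)

    def test_r2_worse_than_mean_is_nan(self):
        # SS_res = 5, SS_tot = 2 -> raw R^2 = -1.5 -> NaN
        assert np.isnan(r2_with_nan((3.0, 3.0, 3.0), (1.0, 2.0, 3.0)))

    def test_r2_zero_variance_actuals_is_nan(self):
        assert np.isnan(r2_with_nan((1.0, 2.0), (5.0, 5.0)))

    def test_length_mismatch_rejected(self, flat_band):
        with pytest.raises(ValueError):
            error_band_metrics([1.0], [1.0, 2.0], flat_band, "t_g")
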