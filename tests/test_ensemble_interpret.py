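"""Ensemble P(t) prediction, distribution scoring, Shapley attribution."""

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

from nucleokin import (
    DistributionParams,
    InductionDataset,
    ModelSpec,
    ensemble_predict,
    evaluate_ensemble,
    feature_attribution,
    generate_hydrodynamic_features,
    invert_cdf,
    model_cdf,
    train_regressors,
    vessel_configs,
)
from nucleokin.ensemble_interpret import PredictedCurve
from nucleokin.ml_correlation import build_feature_matrix


@pytest.fixture(scope="module")
def matrix():
    configs = vessel_configs()
    feats = generate_hydrodynamic_features(configs, seed=0)
    return build_feature_matrix(configs, feats.reset_index())


def _oracle_model(target, value):
    """Duck-typed stand-in model returning a fixed prediction."""
    return SimpleNamespace(target=target,
                           predict=lambda df, v=value: np.full(len(df), v))


class TestEnsemblePredict:
    def test_curve_is_the_model_cdf_of_predicted_params(self, matrix,
                                                        ref_params, ref_volume):
        mJ = _oracle_model("J", np.log10(ref_params.J))
        mT = _oracle_model("t_g", ref_params.t_g)
        grid = np.linspace(0, 60_000, 200)
        curve = ensemble_predict(mJ, mT, matrix.iloc[[0]], ref_volume, grid)
        assert np.allclose(curve.probabilities,
                           model_cdf(grid, ref_params, ref_volume), atol=1e-12)
        assert np.all(curve.probabilities[grid <= ref_params.t_g] == 0)
        assert np.all(np.diff(curve.probabilities) >= 0)

    def test_negative_growth_time_prediction_floored(self, matrix, ref_volume):
        mJ = _oracle_model("J", 0.0)
        mT = _oracle_model("t_g", -500.0)
        curve = ensemble_predict(mJ, mT, matrix.iloc[[0]], ref_volume,
                                 np.linspace(0, 10, 5))
        assert curve.implied_params.t_g == 0.0

    def test_swapped_targets_rejected(self, matrix, ref_volume):
        with pytest.raises(ValueError, match="J model"):
            ensemble_predict(_oracle_model("t_g", 1.0), _oracle_model("J", 1.0),
                             matrix.iloc[[0]], ref_volume, [0.0, 1.0])

    def test_curve_invariants_enforced(self):
        with pytest.raises(ValueError, match="nondecreasing"):
            PredictedCurve("x", np.array([0.0, 1.0, 2.0]),
                           np.array([0.5, 0.2, 0.9]),
                           DistributionParams(J=1.0, t_g=0.0))


class TestEvaluateEnsemble:
    def test_exact_parameters_score_zero(self, ref_params, ref_volume):
        p = np.arange(1, 11) / 11
        times = invert_cdf(p, ref_params, ref_volume)
        ds = InductionDataset("c1", tuple(times), ref_volume)
        grid = np.sort(np.concatenate([[0.0], times, [times.max() * 2]]))
        curve = PredictedCurve("c1", grid,
                               np.atleast_1d(model_cdf(grid, ref_params, ref_volume)),
                               ref_params)
        ev = evaluate_ensemble([curve], [ds], convention="i/(M+1)")
        assert ev.rmse < 1e-8

    def test_constant_half_probability_worked_example(self):
        ds = InductionDataset("c1", (100.0, 200.0, 300.0), 1e-3)
        curve = PredictedCurve("c1", np.array([0.0, 400.0]),
                               np.array([0.5, 0.5]),
                               DistributionParams(J=1.0, t_g=0.0))
        ev = evaluate_ensemble([curve], [ds])
        # residuals (1/6, 1/6, 1/2) -> sqrt((1/36+1/36+1/4)/3)
        assert ev.rmse == pytest.approx(0.3191, abs=2e-4)

    def test_late_onset_prediction_flagged(self):
        ds = InductionDataset("c1", (100.0, 200.0), 1e-3)
        late = DistributionParams(J=1.0, t_g=500.0)
        curve = PredictedCurve("c1", np.array([0.0, 400.0]),
                               np.array([0.0, 0.0]), late)
        ev = evaluate_ensemble([curve], [ds])
        assert ev.late_onset_configs == ("c1",)

    def test_config_mismatch_rejected(self):
        ds = InductionDataset("c1", (100.0,), 1e-3)
        curve = PredictedCurve("other", np.array([0.0, 1.0]),
                               np.array([0.0, 0.1]),
                               DistributionParams(J=1.0, t_g=0.0))
        with pytest.raises(ValueError, match="match"):
            evaluate_ensemble([curve], [ds])


class TestAttribution:
    def test_linear_model_closed_form(self, matrix):
        y = 4.0 * matrix["sr_mean"] + 100.0
        models = train_regressors(matrix, "t_g", y,
                                  [ModelSpec("u", "univariate", feature="sr_mean")],
                                  seed=0)
        model = models["u"]
        train_rows = matrix[matrix["split_label"] == "training_validation"]
        rep = feature_attribution(model, train_rows)
        # phi(x) = beta_std * z(x) = beta_raw * (x - mean(x)) for 1 feature
        x = train_rows["sr_mean"].to_numpy()
        expected = 4.0 * (x - x.mean())
        assert np.allclose(rep.per_row["sr_mean"].to_numpy(), expected, atol=1e-8)
        assert rep.direction("sr_mean") == "positive"

    def test_additivity_axiom_for_tree_model(self, matrix):
        rng = np.random.default_rng(0)
        y = pd.Series(rng.normal(5000, 1000, len(matrix)), index=matrix.index)
        models = train_regressors(matrix, "t_g", y,
                                  [ModelSpec("rf", "random_forest")],
                                  feature_columns=("sr_mean", "volume",
                                                   "impeller_speed"),
                                  seed=0)
        model = models["rf"]
        rows = matrix[matrix["split_label"] == "training_validation"]
        rep = feature_attribution(model, rows)
        preds = model.predict(rows)
        # per-row attributions sum to prediction minus the baseline expectation
        totals = rep.per_row.sum(axis=1).to_numpy() + rep.baseline
        assert np.allclose(totals, preds, atol=1e-8)

    def test_ignored_feature_gets_zero_attribution(self, matrix):
        y = 2.0 * matrix["sr_mean"]
        models = train_regressors(matrix, "t_g", y,
                                  [ModelSpec("lin", "linear")],
                                  feature_columns=("sr_mean", "k_mean"),
                                  seed=0)
        # refit with k_mean frozen: set its coefficient to zero explicitly
        model = models["lin"]
        model.pipeline._est.coef_[1] = 0.0
        rows = matrix[matrix["split_label"] == "training_validation"]
        rep = feature_attribution(model, rows)
        assert rep.mean_abs("k_mean") < 1e-10

    def test_unfitted_model_rejected(self, matrix):
        from nucleokin.ml_correlation import ModelPipeline, TrainedModel
        pipe = ModelPipeline(ModelSpec("lin", "linear"), ["sr_mean"], False, {})
        model = TrainedModel(spec=ModelSpec("lin", "linear"), pipeline=pipe,
                             target="t_g",
                             loo_predictions=pd.Series(dtype=float),
                             loo_rmse=0.0, best_params={})
        with pytest.raises(ValueError, match="fitted"):
            feature_attribution(model, matrix.iloc[:3])
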