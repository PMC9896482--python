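"""Regression workflow correlating hydrodynamics with nucleation kinetics.

Given a feature matrix (vessel volume, impeller speed, the 19 CFD summary
fields, the three classical scale-up scalars, and the categorical impeller
type) and per-configuration targets (nucleation rate J or growth time t_g),
this module provides:

* preprocessing — J modelled as log10(J); numeric features standardized
  using training-split statistics only; impeller type one-hot encoded;
* Pearson-correlation feature reduction (multicollinearity pruning) and a
  PCA variance diagnostic;
* a model zoo (linear, ridge, LASSO, random forest, gradient boosting, kNN)
  plus univariate and constant-value benchmark models, trained with
  leave-one-out validation and small hyperparameter grids chosen by LOO
  RMSE;
* bespoke performance metrics: RMSE, a coefficient of determination that
  reports NaN for fits worse than the mean, and the percentage of
  predictions falling within the estimator error band at M = 5 and M = 20
  observations (bands for J are applied on the log10 scale the models
  predict on).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.exceptions import ConvergenceWarning
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import Lasso, LinearRegression, Ridge
from sklearn.neighbors import KNeighborsRegressor

from .core_model import VesselConfig
from .hydrodynamics import CFD_FEATURE_COLUMNS, DERIVED_COLUMNS
from .synthetic_data import BenchmarkResult

__all__ = [
    "NUMERIC_COLUMNS",
    "ErrorBand",
    "ModelEvaluation",
    "ModelSpec",
    "TrainedModel",
    "DEFAULT_SPECS_J",
    "DEFAULT_SPECS_TG",
    "build_feature_matrix",
    "preprocess",
    "reduce_features",
    "pca_variance",
    "train_regressors",
    "constant_value_models",
    "error_band_metrics",
    "r2_with_nan",
    "band_from_benchmark",
    "evaluation_table",
]

#: Canonical order of the 24 numeric feature columns.
NUMERIC_COLUMNS = ("volume", "impeller_speed") + CFD_FEATURE_COLUMNS + DERIVED_COLUMNS

_CATEGORICAL = "impeller_type"
_ONEHOT = ("impeller_RC", "impeller_PBT")


def build_feature_matrix(configs: list[VesselConfig],
                         features: pd.DataFrame) -> pd.DataFrame:
    """Join vessel metadata with a CFD feature table into one matrix.

    Rows are keyed by config_id and carry the 24 numeric columns, the
    categorical impeller type, and the train/test split label.
    """
    if "config_id" in features.columns:
        features = features.set_index("config_id")
    rows = {}
    for cfg in configs:
        if cfg.config_id not in features.index:
            raise ValueError(f"no features for config {cfg.config_id!r}")
        row = {"volume": cfg.working_volume, "impeller_speed": cfg.impeller_speed}
        row.update(features.loc[cfg.config_id].to_dict())
        row[_CATEGORICAL] = cfg.impeller_type
        row["split_label"] = cfg.split_label
        rows[cfg.config_id] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "config_id"
    missing = [c for c in NUMERIC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"feature matrix missing columns {missing}")
    if df[list(NUMERIC_COLUMNS)].isna().any().any():
        raise ValueError("feature matrix contains missing values")
    return df[list(NUMERIC_COLUMNS) + [_CATEGORICAL, "split_label"]]


def _train_mask(features: pd.DataFrame) -> pd.Series:
    return features["split_label"] == "training_validation"


def _onehot(df: pd.DataFrame) -> pd.DataFrame:
    out = pd.DataFrame(index=df.index)
    out["impeller_RC"] = (df[_CATEGORICAL] == "RC").astype(float)
    out["impeller_PBT"] = (df[_CATEGORICAL] == "PBT").astype(float)
    return out


def preprocess(features: pd.DataFrame, target: str, target_values: pd.Series,
               numeric_columns=None) -> dict:
    """Build model-ready design matrices from the raw feature matrix.

    * target "J": values must be positive and are transformed to log10(J);
      target "t_g": used as-is (seconds).
    * numeric columns are standardized with the mean/variance of the
      training split only (no leakage into the test rows);
    * the impeller type becomes two binary indicator columns.

    Returns a dict with X_train, y_train, X_test, y_test (DataFrames/Series)
    and the standardization statistics actually used.
    """
    if target not in ("J", "t_g"):
        raise ValueError("target must be 'J' or 't_g'")
    cols = list(NUMERIC_COLUMNS if numeric_columns is None else numeric_columns)
    y = target_values.reindex(features.index).astype(float)
    if y.isna().any():
        raise ValueError("target_values missing for some configurations")
    if target == "J":
        if (y <= 0).any():
            raise ValueError("J values must be positive for the log transform")
        y = np.log10(y)
    train = _train_mask(features)
    mu = features.loc[train, cols].mean()
    sd = features.loc[train, cols].std(ddof=0)
    zero = sd[sd == 0]
    if len(zero):
        raise ValueError(f"zero-variance training column: {zero.index[0]!r}")
    X = (features[cols] - mu) / sd
    X = pd.concat([X, _onehot(features)], axis=1)
    return {
        "X_train": X.loc[train], "y_train": y.loc[train],
        "X_test": X.loc[~train], "y_test": y.loc[~train],
        "mean": mu, "std": sd, "columns": list(X.columns), "target": target,
    }


def reduce_features(features: pd.DataFrame, r_max: float = 0.95,
                    numeric_columns=None) -> tuple[pd.DataFrame, list[str]]:
    """Prune numeric columns until no surviving pair correlates above r_max.

    Columns are visited in canonical order; when a candidate's absolute
    Pearson correlation with any already-kept column exceeds ``r_max``, the
    later (candidate) column is dropped.  The categorical impeller-type
    column is always retained.  Returns the reduced matrix and the list of
    dropped columns.
    """
    cols = [c for c in (NUMERIC_COLUMNS if numeric_columns is None else numeric_columns)
            if c in features.columns]
    if len(cols) < 2:
        raise ValueError("need at least 2 numeric columns")
    corr = features[cols].corr(method="pearson").abs()
    kept, dropped = [], []
    for c in cols:
        if any(corr.loc[c, k] > r_max for k in kept):
            dropped.append(c)
        else:
            kept.append(c)
    keep_cols = kept + [c for c in (_CATEGORICAL, "split_label")
                        if c in features.columns]
    return features[keep_cols], dropped


def pca_variance(features: pd.DataFrame, numeric_columns=None) -> np.ndarray:
    """Explained-variance fractions of the standardized numeric features."""
    cols = [c for c in (NUMERIC_COLUMNS if numeric_columns is None else numeric_columns)
            if c in features.columns]
    X = features[cols].to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=0)
    X = (X - X.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    frac = PCA().fit(X).explained_variance_ratio_
    return frac / frac.sum()


# ---------------------------------------------------------------------------
# Metrics

@dataclass(frozen=True)
class ErrorBand:
    """Estimator-error half-widths used as 'experimental error' bands.

    Maps sample size M -> mean absolute estimation error; keys must include
    5 and 20.  For J, the log10-scale MAE is the band applied to model
    predictions (models predict log10 J).
    """

    mae_J_at_M: dict
    mae_tg_at_M: dict
    mae_log10_J_at_M: dict
    source: tuple = ()

    def __post_init__(self) -> None:
        for d in (self.mae_J_at_M, self.mae_tg_at_M, self.mae_log10_J_at_M):
            if not {5, 20} <= set(d):
                raise ValueError("error band needs entries for M = 5 and M = 20")
            if any(v < 0 for v in d.values()):
                raise ValueError("band half-widths must be >= 0")

    def half_width(self, target: str, M: int) -> float:
        return (self.mae_log10_J_at_M if target == "J" else self.mae_tg_at_M)[M]


def band_from_benchmark(results: list[BenchmarkResult],
                        method: str = "mle") -> ErrorBand:
    """Assemble an ErrorBand from estimator-benchmark results."""
    sel = [r for r in results if r.method == method]
    if not sel:
        raise ValueError(f"no benchmark results for method {method!r}")
    return ErrorBand(
        mae_J_at_M={r.M: r.mae_J for r in sel},
        mae_tg_at_M={r.M: r.mae_tg for r in sel},
        mae_log10_J_at_M={r.M: r.mae_log10_J for r in sel},
        source=tuple(sel))


@dataclass(frozen=True)
class ModelEvaluation:
    """RMSE, R^2 (NaN convention) and error-band hit rates for one split."""

    rmse: float
    r2: float
    pct_within_m5: float
    pct_within_m20: float
    split: str

    def __post_init__(self) -> None:
        if self.rmse < 0:
            raise ValueError("rmse must be >= 0")
        if not np.isnan(self.r2) and self.r2 > 1 + 1e-12:
            raise ValueError("r2 must be <= 1 or NaN")
        for p in (self.pct_within_m5, self.pct_within_m20):
            if not (0 <= p <= 100):
                raise ValueError("percentages must lie in [0, 100]")


def r2_with_nan(predictions, actuals) -> float:
    """Coefficient of determination with NaN for worse-than-mean fits.

    A negative raw R^2 means the data are better represented by their mean
    than by the model, and is reported as NaN; zero-variance actuals also
    give NaN.
    """
    p = np.asarray(predictions, dtype=float)
    a = np.asarray(actuals, dtype=float)
    if p.shape != a.shape:
        raise ValueError("predictions and actuals must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 points for R^2")
    ss_tot = float(np.sum((a - a.mean()) ** 2))
    if ss_tot == 0:
        return float("nan")
    r2 = 1.0 - float(np.sum((p - a) ** 2)) / ss_tot
    return r2 if r2 >= 0 else float("nan")


def error_band_metrics(predictions, actuals, band: ErrorBand, target: str,
                       split: str = "train") -> ModelEvaluation:
    """Evaluate predictions with RMSE, R^2 and %-within-error-band metrics.

    Predictions and actuals must be on the scale the model predicts
    (log10 J for J models, seconds for t_g models); the band half-widths
    are interpreted on that same scale.
    """
    p = np.asarray(predictions, dtype=float)
    a = np.asarray(actuals, dtype=float)
    if p.shape != a.shape:
        raise ValueError("predictions and actuals must have equal length")
    err = np.abs(p - a)
    return ModelEvaluation(
        rmse=float(np.sqrt(np.mean((p - a) ** 2))),
        r2=r2_with_nan(p, a) if a.size >= 2 else float("nan"),
        pct_within_m5=float(100.0 * np.mean(err <= band.half_width(target, 5))),
        pct_within_m20=float(100.0 * np.mean(err <= band.half_width(target, 20))),
        split=split)


# ---------------------------------------------------------------------------
# Model zoo

@dataclass(frozen=True)
class ModelSpec:
    """One entry of the model zoo.

    kind: linear | ridge | lasso | random_forest | gradient_boosting | knn
          | univariate | constant
    feature: the single feature name, for univariate benchmarks.
    grouping: "all" or "by_impeller_type", for constant-value benchmarks.
    """

    name: str
    kind: str
    feature: str | None = None
    grouping: str | None = None

    def __post_init__(self) -> None:
        kinds = ("linear", "ridge", "lasso", "random_forest",
                 "gradient_boosting", "knn", "univariate", "constant")
        if self.kind not in kinds:
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.kind == "univariate" and not self.feature:
            raise ValueError("univariate models need a feature name")
        if self.kind == "constant" and self.grouping not in ("all", "by_impeller_type"):
            raise ValueError("constant models need grouping 'all' or 'by_impeller_type'")


# hyperparameter grids; the search minimizes leave-one-out RMSE
_GRIDS = {
    "linear": {},
    "ridge": {"alpha": list(np.logspace(-3, 2, 6))},
    "lasso": {"alpha": list(np.logspace(-3, 2, 6))},
    "random_forest": {"n_estimators": [50, 200], "max_depth": [2, 3]},
    "gradient_boosting": {"n_estimators": [50, 200], "max_depth": [2, 3]},
    "knn": {"n_neighbors": [2, 3, 5]},
    "univariate": {},
    "constant": {},
}


def _make_estimator(kind: str, params: dict, seed: int):
    if kind in ("linear", "univariate"):
        return LinearRegression()
    if kind == "ridge":
        return Ridge(**params)
    if kind == "lasso":
        return Lasso(max_iter=100_000, **params)
    if kind == "random_forest":
        return RandomForestRegressor(random_state=seed, **params)
    if kind == "gradient_boosting":
        return GradientBoostingRegressor(random_state=seed, **params)
    if kind == "knn":
        return KNeighborsRegressor(**params)
    raise ValueError(kind)


class ModelPipeline:
    """Standardize-then-regress pipeline operating on raw feature rows.

    Standardization statistics are fitted from the training rows handed to
    :meth:`fit` and reused verbatim for any later prediction, so test rows
    can never leak into them.  Constant-value models ignore the numeric
    features entirely and predict training group means.
    """

    def __init__(self, spec: ModelSpec, columns, use_onehot: bool,
                 params: dict, seed: int = 0):
        self.spec = spec
        self.columns = list(columns)
        self.use_onehot = use_onehot
        self.params = dict(params)
        self.seed = seed
        self._mu = None
        self._sd = None
        self._est = None
        self._group_means = None

    def _design(self, df: pd.DataFrame) -> np.ndarray:
        X = (df[self.columns] - self._mu) / self._sd
        if self.use_onehot:
            X = pd.concat([X, _onehot(df)], axis=1)
        return X.to_numpy(dtype=float)

    def fit(self, df: pd.DataFrame, y: pd.Series) -> "ModelPipeline":
        if self.spec.kind == "constant":
            if self.spec.grouping == "all":
                self._group_means = {None: float(np.mean(y))}
            else:
                means = y.groupby(df[_CATEGORICAL]).mean()
                if means.isna().any():
                    raise ValueError("empty impeller-type group")
                self._group_means = means.to_dict()
            return self
        mu = df[self.columns].mean()
        sd = df[self.columns].std(ddof=0)
        self._mu, self._sd = mu, sd.where(sd > 0, 1.0)
        self._est = _make_estimator(self.spec.kind, self.params, self.seed)
        with warnings.catch_warnings():
            # near-zero LASSO penalties on second-scale targets converge
            # slowly; the grid search discards such fits by LOO RMSE anyway
            warnings.simplefilter("ignore", ConvergenceWarning)
            self._est.fit(self._design(df), np.asarray(y, dtype=float))
        return self

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        """Predict on the model scale (log10 J for J models, s for t_g)."""
        if self.spec.kind == "constant":
            if self._group_means is None:
                raise RuntimeError("model not fitted")
            if self.spec.grouping == "all":
                return np.full(len(df), self._group_means[None])
            try:
                return df[_CATEGORICAL].map(self._group_means).to_numpy(dtype=float)
            except (KeyError, TypeError) as exc:
                raise ValueError("unseen impeller-type group") from exc
        if self._est is None:
            raise RuntimeError("model not fitted")
        missing = [c for c in self.columns if c not in df.columns]
        if missing:
            raise ValueError(f"feature columns missing: {missing}")
        return np.asarray(self._est.predict(self._design(df)), dtype=float)


@dataclass(frozen=True)
class TrainedModel:
    """A fitted pipeline plus its leave-one-out diagnostics."""

    spec: ModelSpec
    pipeline: ModelPipeline = field(repr=False)
    target: str
    loo_predictions: pd.Series = field(repr=False)
    loo_rmse: float
    best_params: dict

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        return self.pipeline.predict(df)


def _loo_predictions(spec, columns, use_onehot, params, seed,
                     train_df, y_train) -> np.ndarray:
    preds = np.empty(len(train_df))
    for i in range(len(train_df)):
        mask = np.ones(len(train_df), dtype=bool)
        mask[i] = False
        pipe = ModelPipeline(spec, columns, use_onehot, params, seed)
        pipe.fit(train_df.iloc[mask], y_train.iloc[mask])
        preds[i] = pipe.predict(train_df.iloc[[i]])[0]
    return preds


def train_regressors(features: pd.DataFrame, target: str,
                     target_values: pd.Series,
                     model_specs: list[ModelSpec],
                     feature_columns=None, loo: bool = True,
                     seed: int = 0) -> dict[str, TrainedModel]:
    """Train the model zoo with leave-one-out hyperparameter selection.

    ``feature_columns`` is the (typically reduced) numeric column set for
    multivariate models; univariate and constant benchmarks ignore it.  For
    each spec and each grid point, leave-one-out predictions over the
    training split are computed; the grid point with the lowest LOO RMSE
    wins and is refitted on the full training split.
    """
    train = features.loc[_train_mask(features)]
    if len(train) < 3:
        raise ValueError("training split needs at least 3 rows")
    y = target_values.reindex(features.index).astype(float)
    if target == "J":
        if (y <= 0).any():
            raise ValueError("J values must be positive")
        y = np.log10(y)
    y_train = y.loc[train.index]

    if feature_columns is None:
        feature_columns = [c for c in NUMERIC_COLUMNS if c in features.columns]

    out = {}
    for spec in model_specs:
        if spec.kind == "univariate":
            columns, use_onehot = [spec.feature], False
            if spec.feature not in features.columns:
                raise ValueError(f"unknown univariate feature {spec.feature!r}")
        elif spec.kind == "constant":
            columns, use_onehot = [], False
        else:
            columns, use_onehot = list(feature_columns), True

        grid = _GRIDS[spec.kind]
        keys = list(grid)
        best = None
        for combo in itertools.product(*(grid[k] for k in keys)) or [()]:
            params = dict(zip(keys, combo))
            if loo:
                preds = _loo_predictions(spec, columns, use_onehot, params,
                                         seed, train, y_train)
            else:
                pipe = ModelPipeline(spec, columns, use_onehot, params, seed)
                pipe.fit(train, y_train)
                preds = pipe.predict(train)
            rmse = float(np.sqrt(np.mean((preds - y_train.to_numpy()) ** 2)))
            if best is None or rmse < best[0]:
                best = (rmse, params, preds)
        loo_rmse, params, preds = best
        pipe = ModelPipeline(spec, columns, use_onehot, params, seed)
        pipe.fit(train, y_train)
        out[spec.name] = TrainedModel(
            spec=spec, pipeline=pipe, target=target,
            loo_predictions=pd.Series(preds, index=train.index),
            loo_rmse=loo_rmse, best_params=params)
    return out


def constant_value_models(target_values: pd.Series, features: pd.DataFrame,
                          grouping: str = "all") -> pd.Series:
    """Predictions of the constant-value benchmark on the training split.

    grouping="all" predicts the single training mean everywhere;
    grouping="by_impeller_type" predicts the training mean of each impeller
    class.  Raises on empty groups.
    """
    train = features.loc[_train_mask(features)]
    y = target_values.reindex(train.index).astype(float)
    if grouping == "all":
        return pd.Series(float(y.mean()), index=features.index)
    if grouping == "by_impeller_type":
        means = y.groupby(train[_CATEGORICAL]).mean()
        seen = set(means.index)
        have = set(features[_CATEGORICAL].unique())
        if not have <= seen:
            raise ValueError(f"empty group(s): {sorted(have - seen)}")
        return features[_CATEGORICAL].map(means).astype(float)
    raise ValueError(f"unknown grouping {grouping!r}")


#: Default model zoos mirroring the study's benchmark + multivariate lineup.
DEFAULT_SPECS_J = (
    ModelSpec("J1", "univariate", feature="reynolds"),
    ModelSpec("J2", "univariate", feature="tip_speed"),
    ModelSpec("J3", "univariate", feature="specific_power"),
    ModelSpec("J4", "univariate", feature="radial_mean"),
    ModelSpec("J5", "ridge"),
    ModelSpec("J6", "lasso"),
    ModelSpec("J7", "random_forest"),
    ModelSpec("J8", "knn"),
    ModelSpec("J9", "gradient_boosting"),
)

DEFAULT_SPECS_TG = (
    ModelSpec("T1", "constant", grouping="all"),
    ModelSpec("T2", "constant", grouping="by_impeller_type"),
    ModelSpec("T3", "univariate", feature="impeller_speed"),
    ModelSpec("T4", "univariate", feature="tip_speed"),
    ModelSpec("T5", "ridge"),
    ModelSpec("T6", "lasso"),
    ModelSpec("T7", "random_forest"),
    ModelSpec("T8", "knn"),
    ModelSpec("T9", "gradient_boosting"),
)


def evaluation_table(models: dict[str, TrainedModel], features: pd.DataFrame,
                     target_values: pd.Series, band: ErrorBand,
                     target: str) -> pd.DataFrame:
    """Per-model evaluation table (train = LOO metrics, test = held-out).

    Columns mirror the published summary tables: model, type, features,
    train RMSE / R^2, % within the M=5 and M=20 error bands (training LOO
    predictions), and test RMSE / R^2.
    """
    train = _train_mask(features)
    y = target_values.reindex(features.index).astype(float)
    if target == "J":
        y = np.log10(y)
    rows = []
    for name, model in models.items():
        ev_train = error_band_metrics(model.loo_predictions.to_numpy(),
                                      y.loc[train].to_numpy(), band, target,
                                      split="train")
        feats = (model.spec.feature if model.spec.kind == "univariate"
                 else "" if model.spec.kind == "constant" else "reduced")
        row = {"model": name, "type": model.spec.kind, "features": feats,
               "train_rmse": ev_train.rmse, "train_r2": ev_train.r2,
               "pct_within_m5": ev_train.pct_within_m5,
               "pct_within_m20": ev_train.pct_within_m20}
        if (~train).any():
            p_test = model.predict(features.loc[~train])
            ev_test = error_band_metrics(p_test, y.loc[~train].to_numpy(),
                                         band, target, split="test")
            row["test_rmse"] = ev_test.rmse
            row["test_r2"] = ev_test.r2
        rows.append(row)
    return pd.DataFrame(rows).set_index("model")
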