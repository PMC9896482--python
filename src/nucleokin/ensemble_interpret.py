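"""Ensembles predicting induction-time distributions, and model attribution.

A J-model and a t_g-model trained on hydrodynamic features can be combined:
their per-configuration predictions (J back-transformed from log10 space,
t_g floored at zero) are plugged into the shifted-exponential CDF, giving a
predicted cumulative probability of nucleation P(t) for a configuration that
has never been measured.  Predicted curves are scored against observed
induction-time series by taking residuals at the observed times between the
empirical cumulative probability and the predicted curve, pooled across all
configurations.

Feature attributions are exact interventional Shapley values computed by
coalition enumeration against a background set (the training split): for
each feature subset S the value function is the model prediction averaged
over background rows with the features in S fixed to the explained row.
This satisfies the additivity axiom exactly and reduces to
``beta * (x - mean(x))`` for linear models.  For more than
``_EXACT_LIMIT`` features a seeded permutation-sampling estimate is used
instead.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_model import DistributionParams, InductionDataset, empirical_cdf, model_cdf
from .ml_correlation import TrainedModel

__all__ = [
    "PredictedCurve",
    "EnsembleEvaluation",
    "AttributionReport",
    "ensemble_predict",
    "evaluate_ensemble",
    "feature_attribution",
]

_EXACT_LIMIT = 12


@dataclass(frozen=True)
class PredictedCurve:
    """An ensemble-predicted cumulative probability over a time grid."""

    config_id: str
    time_grid: np.ndarray = field(repr=False)
    probabilities: np.ndarray = field(repr=False)
    implied_params: DistributionParams

    def __post_init__(self) -> None:
        t = np.asarray(self.time_grid, dtype=float)
        p = np.asarray(self.probabilities, dtype=float)
        if t.shape != p.shape or t.ndim != 1:
            raise ValueError("time_grid and probabilities must be equal-length 1-D")
        if np.any(np.diff(t) < 0):
            raise ValueError("time_grid must be nondecreasing")
        if np.any(p < 0) or np.any(p > 1) or np.any(np.diff(p) < -1e-12):
            raise ValueError("probabilities must be nondecreasing within [0, 1]")
        object.__setattr__(self, "time_grid", t)
        object.__setattr__(self, "probabilities", p)

    def interp(self, t) -> np.ndarray:
        """Predicted probability at arbitrary times (linear interpolation)."""
        return np.interp(np.asarray(t, dtype=float), self.time_grid,
                         self.probabilities)


def ensemble_predict(model_J: TrainedModel, model_tg: TrainedModel,
                     features_row: pd.DataFrame, volume_V: float,
                     time_grid) -> PredictedCurve:
    """Predict one configuration's induction-time distribution.

    ``features_row`` is a single-row feature frame; the J model's log10
    prediction is exponentiated and the t_g prediction floored at zero, and
    the model CDF is evaluated on the grid.
    """
    if len(features_row) != 1:
        raise ValueError("features_row must contain exactly one row")
    if model_J.target != "J" or model_tg.target != "t_g":
        raise ValueError("ensemble needs a J model and a t_g model")
    log10_J = float(model_J.predict(features_row)[0])
    t_g = max(float(model_tg.predict(features_row)[0]), 0.0)
    params = DistributionParams(J=10.0 ** log10_J, t_g=t_g)
    grid = np.asarray(time_grid, dtype=float)
    probs = np.atleast_1d(model_cdf(grid, params, volume_V))
    return PredictedCurve(config_id=str(features_row.index[0]),
                          time_grid=grid, probabilities=probs,
                          implied_params=params)


@dataclass(frozen=True)
class EnsembleEvaluation:
    """Aggregate and per-configuration scores for a set of predicted curves.

    ``rmse`` pools all residuals before the square root (the headline
    number); ``rmse_mean_of_configs`` averages per-configuration RMSEs and
    is reported alongside.  ``late_onset_configs`` flags configurations
    whose predicted growth time exceeds every observed induction time, i.e.
    the ensemble predicts P = 0 at all observations.
    """

    rmse: float
    r2: float
    rmse_per_config: dict
    rmse_mean_of_configs: float
    late_onset_configs: tuple


def evaluate_ensemble(curves: list[PredictedCurve],
                      observed: list[InductionDataset],
                      convention: str = "i/M") -> EnsembleEvaluation:
    """Score predicted curves against observed induction-time series.

    Residuals are taken at each observed induction time between the
    empirical cumulative probability and the predicted curve interpolated on
    its grid; RMSE pools residuals across all configurations and R^2 uses
    the worse-than-mean NaN convention on the pooled pairs.
    """
    by_id = {c.config_id: c for c in curves}
    if len(by_id) != len(curves):
        raise ValueError("duplicate config_ids among curves")
    ids = [ds.config_id for ds in observed]
    if set(ids) != set(by_id) or len(ids) != len(curves):
        raise ValueError("curves and observed datasets must match one-to-one")
    from .ml_correlation import r2_with_nan  # local to avoid cycle at import

    pooled_p, pooled_a, per_cfg, late = [], [], {}, []
    for ds in observed:
        curve = by_id[ds.config_id]
        t, p_emp = empirical_cdf(ds, convention)
        p_pred = curve.interp(t)
        res = p_pred - p_emp
        per_cfg[ds.config_id] = float(np.sqrt(np.mean(res**2)))
        pooled_p.append(p_pred)
        pooled_a.append(p_emp)
        if curve.implied_params.t_g > ds.times_array.max():
            late.append(ds.config_id)
    p = np.concatenate(pooled_p)
    a = np.concatenate(pooled_a)
    return EnsembleEvaluation(
        rmse=float(np.sqrt(np.mean((p - a) ** 2))),
        r2=r2_with_nan(p, a),
        rmse_per_config=per_cfg,
        rmse_mean_of_configs=float(np.mean(list(per_cfg.values()))),
        late_onset_configs=tuple(late))


# ---------------------------------------------------------------------------
# Shapley attribution

@dataclass(frozen=True)
class AttributionReport:
    """Per-feature Shapley summary for a fitted model.

    ``table`` has one row per feature: mean absolute attribution, the signed
    high-value direction ('positive' if larger feature values push the
    prediction up), and the feature/attribution correlation backing it.
    ``per_row`` holds the raw per-row attributions; their row sums equal
    prediction minus baseline (additivity).
    """

    table: pd.DataFrame = field(repr=False)
    per_row: pd.DataFrame = field(repr=False)
    baseline: float
    exact: bool

    def mean_abs(self, feature: str) -> float:
        return float(self.table.loc[feature, "mean_abs_attribution"])

    def direction(self, feature: str) -> str:
        return str(self.table.loc[feature, "direction"])


def _players(model: TrainedModel) -> list[str]:
    cols = list(model.pipeline.columns)
    if model.pipeline.use_onehot:
        cols.append("impeller_type")
    return cols


def _needed_columns(model: TrainedModel) -> list[str]:
    cols = list(model.pipeline.columns)
    if model.pipeline.use_onehot:
        cols.append("impeller_type")
    return cols


def _coalition_values(model, x_row: pd.Series, background: pd.DataFrame,
                      subsets: list[tuple]) -> np.ndarray:
    """v(S) = mean prediction over background rows with S pinned to x_row.

    All coalitions are evaluated with a single model call: the background is
    tiled once per subset and the pinned columns overwritten blockwise.
    """
    needed = _needed_columns(model)
    n_bg = len(background)
    data = {c: np.tile(background[c].to_numpy(), len(subsets)) for c in needed}
    for si, subset in enumerate(subsets):
        block = slice(si * n_bg, (si + 1) * n_bg)
        for col in subset:
            data[col][block] = x_row[col]
    preds = model.predict(pd.DataFrame(data))
    return preds.reshape(len(subsets), n_bg).mean(axis=1)


def _exact_shapley_row(model, x_row, background, players) -> np.ndarray:
    p = len(players)
    subsets = [s for r in range(p + 1)
               for s in itertools.combinations(players, r)]
    values = dict(zip((frozenset(s) for s in subsets),
                      _coalition_values(model, x_row, background, subsets)))
    phi = np.zeros(p)
    fact = math.factorial
    for j, pj in enumerate(players):
        others = [q for q in players if q != pj]
        for r in range(p):
            w = fact(r) * fact(p - r - 1) / fact(p)
            for subset in itertools.combinations(others, r):
                s = frozenset(subset)
                phi[j] += w * (values[s | {pj}] - values[s])
    return phi


def _sampled_shapley_row(model, x_row, background, players, rng,
                         n_perm: int = 200) -> np.ndarray:
    p = len(players)
    phi = np.zeros(p)
    for _ in range(n_perm):
        order = rng.permutation(p)
        chain = [tuple(players[j] for j in order[:k]) for k in range(p + 1)]
        vals = _coalition_values(model, x_row, background, chain)
        for k, j in enumerate(order):
            phi[j] += vals[k + 1] - vals[k]
    return phi / n_perm


def feature_attribution(model: TrainedModel, table: pd.DataFrame,
                        background: pd.DataFrame | None = None,
                        seed: int = 0) -> AttributionReport:
    """Interventional Shapley attributions for a fitted regression model.

    ``table`` holds the rows to explain; ``background`` (default: the rows
    of ``table``) supplies the reference distribution.  The categorical
    impeller type is treated as a single player.  Exact enumeration is used
    up to 12 players, seeded permutation sampling beyond.
    """
    if model.pipeline.spec.kind == "constant":
        raise ValueError("constant-value models have no feature attributions")
    if model.pipeline._est is None:
        raise ValueError("model must be fitted before attribution")
    background = table if background is None else background
    players = _players(model)
    exact = len(players) <= _EXACT_LIMIT
    rng = np.random.default_rng(seed)
    rows = []
    for _, x_row in table.iterrows():
        if exact:
            rows.append(_exact_shapley_row(model, x_row, background, players))
        else:
            rows.append(_sampled_shapley_row(model, x_row, background,
                                             players, rng))
    per_row = pd.DataFrame(rows, index=table.index, columns=players)
    baseline = float(_coalition_values(model, table.iloc[0], background, [()])[0])

    summary = []
    for col in players:
        attr = per_row[col].to_numpy()
        if col == "impeller_type":
            vals = (table["impeller_type"] == "RC").to_numpy(dtype=float)
        else:
            vals = table[col].to_numpy(dtype=float)
        mean_abs = float(np.mean(np.abs(attr)))
        if mean_abs < 1e-12 or np.std(vals) == 0 or np.std(attr) == 0:
            corr, direction = 0.0, "none"
        else:
            corr = float(np.corrcoef(vals, attr)[0, 1])
            direction = "positive" if corr > 0 else "negative"
        summary.append({"feature": col, "mean_abs_attribution": mean_abs,
                        "direction": direction, "correlation": corr})
    tab = pd.DataFrame(summary).set_index("feature") \
        .sort_values("mean_abs_attribution", ascending=False)
    return AttributionReport(table=tab, per_row=per_row,
                             baseline=baseline, exact=exact)
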