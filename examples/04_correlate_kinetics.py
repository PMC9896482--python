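"""Correlate fitted kinetics with hydrodynamic features.

Fabricates a complete study (features + induction times with a known
ground-truth mapping), fits (J, t_g) per configuration by MLE, prunes
collinear features at |r| <= 0.95, and trains the model zoo — univariate
and constant-value benchmarks plus linear, ridge, LASSO, random forest,
gradient boosting and kNN — with leave-one-out validation on the 14
training configurations.  Error bands come from the estimator benchmark:
a prediction counts as a hit if it lands within the typical estimation
error at M = 5 (or 20) observations.
"""

import pandas as pd

from nucleokin import (
    estimator_benchmark, fit_mle, generate_study,
    reduce_features, train_regressors,
)
from nucleokin.ml_correlation import (
    DEFAULT_SPECS_J, band_from_benchmark, build_feature_matrix, evaluation_table,
)

study = generate_study(seed=0)
matrix = build_feature_matrix(list(study.configs), study.features.reset_index())

kinetics = pd.Series({ds.config_id: fit_mle(ds).params.J
                      for ds in study.datasets}, name="J")

reduced, dropped = reduce_features(matrix, r_max=0.95)
feature_cols = [c for c in reduced.columns
                if c not in ("impeller_type", "split_label")]
print(f"feature reduction: kept {feature_cols}, dropped {len(dropped)} of "
      f"{len(feature_cols) + len(dropped)} numeric columns\n")

band = band_from_benchmark(
    estimator_benchmark(n_datasets=300, methods=("mle",), seed=0), "mle")
models = train_regressors(matrix, "J", kinetics, list(DEFAULT_SPECS_J),
                          feature_columns=feature_cols, seed=0)
table = evaluation_table(models, matrix, kinetics, band, "J")
print(table.to_string(float_format="%.3g"))
print("\nRMSE/R^2 on the log10(J) scale models predict on; train columns "
      "are leave-one-out, test columns the 3 held-out configurations. "
      "NaN R^2 marks fits worse than predicting the mean.")
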