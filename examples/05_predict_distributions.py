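"""Predict induction-time distributions from hydrodynamics alone.

Runs the full pipeline on a fabricated study, then shows what it produces:
the learned J/t_g model pair ensembled through the induction-time CDF into
P(t) curves for the three held-out configurations, scored against their
observed series, compared with a no-CFD benchmark (tip-speed univariate J
+ per-impeller constant t_g), and interpreted with exact Shapley feature
attributions.
"""

import dataclasses

import pandas as pd

from nucleokin import RunConfig, run_pipeline

cfg = RunConfig(seed=1)
cfg.io.out_dir = "scratch/example_run"
cfg.benchmark = dataclasses.replace(cfg.benchmark, n_datasets=300)
out = run_pipeline(cfg)

summary = pd.read_csv(out / "ensemble_summary.csv")
print(summary.to_string(index=False, float_format="%.3g"))
print("\nPooled RMSE is over empirical-vs-predicted cumulative probability "
      "at every observed induction time of the 3 testing configurations; "
      "a late_onset entry means that ensemble predicted zero nucleation "
      "probability across all observed times for that configuration.\n")

for tag, target in (("J", "log10 J"), ("tg", "t_g")):
    att = pd.read_csv(out / f"attribution_{tag}.csv")
    print(f"top features for {target}:")
    print(att.head(4).to_string(index=False, float_format="%.3g"))
    print()
print("direction = sign of the feature's high-value effect on the "
      "prediction (exact interventional Shapley over the training split).")
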