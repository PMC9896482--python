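"""End-to-end orchestration: estimate, correlate, ensemble, explain.

A :class:`RunConfig` (YAML round-trippable) fixes every knob and a single
root seed; :func:`run_pipeline` executes the stages in analysis order —

1. inputs: fabricate a synthetic study, or load induction-time, feature and
   vessel-configuration CSVs;
2. kinetics: estimate (J, t_g) per configuration with the configured
   estimator;
3. error bands: estimator benchmark on synthetic series at the study's
   reference truth, giving MAE bands at each sample size;
4. correlation: feature reduction, model zoo training with leave-one-out
   grids, evaluation tables for J and t_g;
5. ensemble: predict P(t) for the testing configurations with the chosen
   (or best-LOO) model pair and with the no-CFD benchmark pair, and score
   both against the observed series;
6. attribution: Shapley feature importances for the ensemble members.

Every intermediate table is written to the run directory; a manifest
records seeds, stage wall times and package versions.  Any stage failure
aborts with the stage name; partial outputs are preserved.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .core_model import VesselConfig, read_induction_csv, write_induction_csv
from .estimators import fit
from .fixtures import load_fixtures, vessel_configs
from .synthetic_data import (
    DEFAULT_M_LIST,
    DistributionParams,
    StudyNoise,
    benchmark_frame,
    estimator_benchmark,
    generate_study,
)
from .hydrodynamics import validate_feature_frame
from .ml_correlation import (
    DEFAULT_SPECS_J,
    DEFAULT_SPECS_TG,
    band_from_benchmark,
    build_feature_matrix,
    evaluation_table,
    reduce_features,
    train_regressors,
)
from .ensemble_interpret import ensemble_predict, evaluate_ensemble, feature_attribution

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "load_fixtures",
           "vessel_configs", "write_vessel_csv", "read_vessel_csv"]


class PipelineError(RuntimeError):
    """A stage failure; the message names the stage."""


@dataclass
class EstimatorSettings:
    method: str = "mle"
    n_boot: int = 1000
    bounds_J: tuple = (0.01, 20.0)
    bounds_tg: tuple = (3000.0, 30000.0)
    convention: str = "i/M"


@dataclass
class BenchmarkSettings:
    true_J: float = 0.1
    true_tg: float = 10_000.0
    true_volume: float = 0.01
    M_list: tuple = tuple(DEFAULT_M_LIST)
    n_datasets: int = 1000
    methods: tuple = ("mle",)
    n_boot: int = 1000


@dataclass
class MLSettings:
    r_max: float = 0.95
    band_method: str = "mle"


@dataclass
class SyntheticSettings:
    enabled: bool = True
    n_configs: int = 17
    n_times: int = 80
    sigma_log10_J: float = 0.03
    sigma_tg: float = 300.0


@dataclass
class IOSettings:
    out_dir: str = "run"
    induction_csv: str | None = None
    features_csv: str | None = None
    configs_csv: str | None = None


@dataclass
class RunConfig:
    """Complete, serializable configuration for one pipeline run.

    ``ensemble`` is either "best_loo" (pick the multivariate J and t_g
    models with the lowest leave-one-out RMSE) or an explicit "Jx+Ty" pair.
    """

    seed: int = 0
    estimator: EstimatorSettings = field(default_factory=EstimatorSettings)
    benchmark: BenchmarkSettings = field(default_factory=BenchmarkSettings)
    ml: MLSettings = field(default_factory=MLSettings)
    synthetic: SyntheticSettings = field(default_factory=SyntheticSettings)
    ensemble: str = "best_loo"
    io: IOSettings = field(default_factory=IOSettings)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(asdict(self)), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            seed=raw.get("seed", 0),
            estimator=_load_dc(EstimatorSettings, raw.get("estimator", {})),
            benchmark=_load_dc(BenchmarkSettings, raw.get("benchmark", {})),
            ml=_load_dc(MLSettings, raw.get("ml", {})),
            synthetic=_load_dc(SyntheticSettings, raw.get("synthetic", {})),
            ensemble=raw.get("ensemble", "best_loo"),
            io=_load_dc(IOSettings, raw.get("io", {})),
        )


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _load_dc(cls, raw: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name in raw:
            v = raw[f.name]
            kwargs[f.name] = tuple(v) if isinstance(v, list) else v
    return cls(**kwargs)


def _stage_seeds(root_seed: int, names) -> dict[str, int]:
    state = np.random.SeedSequence(root_seed).generate_state(len(names))
    return {n: int(s % 2**31) for n, s in zip(names, state)}


def write_vessel_csv(configs: list[VesselConfig], path) -> None:
    pd.DataFrame([asdict(c) for c in configs]).to_csv(path, index=False)


def read_vessel_csv(path) -> list[VesselConfig]:
    df = pd.read_csv(path)
    return [VesselConfig(**{f.name: row[f.name]
                            for f in dataclasses.fields(VesselConfig)})
            for _, row in df.iterrows()]


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis; returns the run directory path."""
    out = Path(config.io.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed,
                         ["study", "benchmark", "train", "attribution"])
    manifest = {"package_version": _pkg_version, "root_seed": config.seed,
                "stage_seeds": seeds, "stages": {}}
    config.to_yaml(out / "config.yaml")

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:  # noqa: BLE001 - reported with stage name
                manifest["stages"][name] = {"status": "failed", "error": str(exc)}
                (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            manifest["stages"][name] = {
                "status": "ok", "wall_s": round(time.perf_counter() - t0, 3)}
            return result
        return deco

    # -- stage: inputs ------------------------------------------------------
    def _inputs():
        if config.synthetic.enabled:
            study = generate_study(
                n_configs=config.synthetic.n_configs,
                noise=StudyNoise(n_times=config.synthetic.n_times,
                                 sigma_log10_J=config.synthetic.sigma_log10_J,
                                 sigma_tg=config.synthetic.sigma_tg),
                seed=seeds["study"])
            configs = list(study.configs)
            features = study.features
            datasets = list(study.datasets)
        else:
            for name, p in (("configs_csv", config.io.configs_csv),
                            ("induction_csv", config.io.induction_csv),
                            ("features_csv", config.io.features_csv)):
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"required input {name} missing: {p}")
            configs = read_vessel_csv(config.io.configs_csv)
            datasets = read_induction_csv(
                config.io.induction_csv,
                volumes={c.config_id: c.volume_m3 for c in configs})
            features = validate_feature_frame(
                pd.read_csv(config.io.features_csv), require_derived=True)
        write_induction_csv(datasets, out / "induction_times.csv")
        features.to_csv(out / "features.csv")
        write_vessel_csv(configs, out / "vessel_configs.csv")
        return configs, features, datasets

    configs, features, datasets = stage("inputs")(_inputs)

    # -- stage: kinetics ----------------------------------------------------
    def _kinetics():
        rows = []
        est = config.estimator
        for ds in datasets:
            res = fit(ds, est.method, n_boot=est.n_boot, seed=seeds["study"],
                      bounds_J=tuple(est.bounds_J),
                      bounds_tg=tuple(est.bounds_tg),
                      convention=est.convention)
            rows.append({"config_id": ds.config_id, "M": ds.M,
                         "J": res.params.J, "t_g": res.params.t_g,
                         "fit_rmse": res.fit_rmse})
        df = pd.DataFrame(rows).set_index("config_id")
        df.to_csv(out / "kinetics_estimates.csv")
        return df

    kinetics = stage("kinetics")(_kinetics)

    # -- stage: error bands -------------------------------------------------
    def _bands():
        b = config.benchmark
        results = estimator_benchmark(
            true_params=DistributionParams(J=b.true_J, t_g=b.true_tg),
            volume_V=b.true_volume, M_list=tuple(b.M_list),
            n_datasets=b.n_datasets, methods=tuple(b.methods),
            seed=seeds["benchmark"], n_boot=b.n_boot)
        benchmark_frame(results).to_csv(out / "estimator_benchmark.csv",
                                        index=False)
        return band_from_benchmark(results, method=config.ml.band_method)

    band = stage("bands")(_bands)

    # -- stage: correlation -------------------------------------------------
    def _correlate():
        matrix = build_feature_matrix(configs, features.reset_index())
        reduced, dropped = reduce_features(matrix, r_max=config.ml.r_max)
        feature_cols = [c for c in reduced.columns
                        if c not in ("impeller_type", "split_label")]
        (out / "reduced_features.json").write_text(
            json.dumps({"kept": feature_cols, "dropped": dropped}, indent=2))
        models = {}
        for target, specs in (("J", DEFAULT_SPECS_J), ("t_g", DEFAULT_SPECS_TG)):
            y = kinetics["J"] if target == "J" else kinetics["t_g"]
            trained = train_regressors(matrix, target, y, list(specs),
                                       feature_columns=feature_cols,
                                       seed=seeds["train"])
            evaluation_table(trained, matrix, y, band, target).to_csv(
                out / f"evaluation_{'J' if target == 'J' else 'tg'}.csv")
            models[target] = trained
        return matrix, models

    matrix, models = stage("correlation")(_correlate)

    # -- stage: ensemble ----------------------------------------------------
    def _ensemble():
        test_ids = matrix.index[matrix["split_label"] == "testing"]
        if len(test_ids) == 0:
            raise ValueError("no testing configurations to ensemble over")
        multivariate = ("ridge", "lasso", "random_forest",
                        "gradient_boosting", "knn", "linear")
        if config.ensemble == "best_loo":
            mj = min((m for m in models["J"].values()
                      if m.spec.kind in multivariate), key=lambda m: m.loo_rmse)
            mt = min((m for m in models["t_g"].values()
                      if m.spec.kind in multivariate), key=lambda m: m.loo_rmse)
        else:
            j_name, t_name = config.ensemble.split("+")
            mj = models["J"][j_name.strip()]
            mt = models["t_g"][t_name.strip()]
        bench_j = models["J"]["J2"]
        bench_t = models["t_g"]["T2"]

        vol = {ds.config_id: ds.volume_V for ds in datasets}
        obs = [ds for ds in datasets if ds.config_id in set(test_ids)]
        rows, summaries = [], []
        for label, mJ, mT in (("ensemble", mj, mt),
                              ("no_cfd_benchmark", bench_j, bench_t)):
            curves = []
            for cid in test_ids:
                ds = next(d for d in obs if d.config_id == cid)
                tmax = ds.times_array.max()
                grid = np.linspace(0.0, 1.1 * tmax, 512)
                curves.append(ensemble_predict(mJ, mT, matrix.loc[[cid]],
                                               vol[cid], grid))
            ev = evaluate_ensemble(curves, obs,
                                   convention=config.estimator.convention)
            for c in curves:
                for t, p in zip(c.time_grid, c.probabilities):
                    rows.append({"ensemble": label, "config_id": c.config_id,
                                 "t_s": t, "P": p})
            summaries.append({
                "ensemble": label,
                "model_J": mJ.spec.name, "model_tg": mT.spec.name,
                "rmse": ev.rmse, "r2": ev.r2,
                "rmse_mean_of_configs": ev.rmse_mean_of_configs,
                "late_onset_configs": ";".join(ev.late_onset_configs)})
        pd.DataFrame(rows).to_csv(out / "predicted_curves.csv", index=False)
        pd.DataFrame(summaries).to_csv(out / "ensemble_summary.csv", index=False)
        return mj, mt

    model_j, model_t = stage("ensemble")(_ensemble)

    # -- stage: attribution -------------------------------------------------
    def _attr():
        train_rows = matrix.loc[matrix["split_label"] == "training_validation"]
        for model, tag in ((model_j, "J"), (model_t, "tg")):
            rep = feature_attribution(model, train_rows,
                                      seed=seeds["attribution"])
            rep.table.to_csv(out / f"attribution_{tag}.csv")

    stage("attribution")(_attr)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
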