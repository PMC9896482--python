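"""Synthetic induction times, estimator benchmarking, and fabricated studies.

Three jobs live here:

1. **Induction-time sampling.**  Draw uniform cumulative probabilities
   u ~ U[0, 1) and invert the shifted-exponential CDF, giving exact samples
   from the induction-time distribution for known (J, t_g, V).

2. **Estimator benchmark.**  Generate many synthetic series at each of
   several sample sizes M, run each estimator, and report the mean absolute
   error of the recovered J and t_g against the generating truth.  The
   default conditions (J = 0.1 #/(m^3 s), V = 0.01 m^3, t_g = 10,000 s,
   M in {5, 10, 20, 40, 80}, 1000 datasets per M) are the ones used to
   choose an estimator for sparse experimental series; the resulting MAE
   curves double as experimental error bands for the ML stage.

3. **Fabricated studies.**  Real CFD feature tables and raw induction times
   for the published configurations are not deposited, so end-to-end testing
   of the correlation/ensemble stages uses a fabricated study: CFD-like
   feature tables with the schema, positivity, quantile ordering and strong
   collinearity of real ones, plus a known ground-truth mapping from
   features to (J, t_g) that generates every configuration's induction
   times.  The fabrication recipe is a fixture and makes no claim to CFD
   physics.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_model import DistributionParams, InductionDataset, VesselConfig, invert_cdf
from .estimators import FitError, fit_direct, bootstrap_fit, _mle_over_resamples
from .fixtures import vessel_configs
from .hydrodynamics import (
    CFD_FEATURE_COLUMNS,
    FluidProperties,
    IPA_SOLUTION,
    derived_scalars,
    validate_feature_frame,
)

__all__ = [
    "BenchmarkResult",
    "StudyNoise",
    "SyntheticStudy",
    "DEFAULT_TRUE_PARAMS",
    "DEFAULT_TRUE_VOLUME",
    "DEFAULT_M_LIST",
    "generate_induction_times",
    "estimator_benchmark",
    "benchmark_frame",
    "generate_hydrodynamic_features",
    "generate_study",
]

#: Default generating truth for the estimator benchmark, comparable to the
#: largest-scale (10 L) experimental series.
DEFAULT_TRUE_PARAMS = DistributionParams(J=0.1, t_g=10_000.0)
DEFAULT_TRUE_VOLUME = 0.01  # m^3
DEFAULT_M_LIST = (5, 10, 20, 40, 80)

BENCHMARK_METHODS = ("direct", "mle", "bootstrap", "mle_bootstrap")


@dataclass(frozen=True)
class BenchmarkResult:
    """MAE of one estimator at one sample size against known truth.

    ``mae_log10_J`` is the mean absolute error of log10(J_hat); it is the
    natural band half-width when models predict J on a log scale.
    """

    method: str
    M: int
    mae_J: float
    mae_tg: float
    mae_log10_J: float
    n_datasets: int
    n_failed: int
    true_params: DistributionParams
    true_volume: float

    def __post_init__(self) -> None:
        for v in (self.mae_J, self.mae_tg, self.mae_log10_J):
            if not (np.isfinite(v) and v >= 0):
                raise ValueError("MAE values must be finite and >= 0")
        if self.n_datasets < 1:
            raise ValueError("n_datasets must be >= 1")


def generate_induction_times(params: DistributionParams, volume_V: float,
                             M: int, seed) -> InductionDataset:
    """Sample M induction times by inverse-transform from the model CDF.

    ``seed`` may be an int or a numpy Generator/SeedSequence.  All samples
    are >= t_g by construction; u = 1 is excluded so times stay finite.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    rng = np.random.default_rng(seed)
    u = rng.random(M)  # [0, 1)
    times = invert_cdf(u, params, volume_V)
    # guard the measure-zero u = 0 draw when t_g = 0 (times must be > 0)
    times = np.maximum(np.atleast_1d(times), np.finfo(float).tiny)
    return InductionDataset(config_id="synthetic", times=tuple(times),
                            volume_V=volume_V)


def _sample_time_matrix(rng, params, volume_V, n_datasets, M):
    u = rng.random((n_datasets, M))
    return params.t_g - np.log1p(-u) / (params.J * volume_V)


def estimator_benchmark(true_params: DistributionParams = DEFAULT_TRUE_PARAMS,
                        volume_V: float = DEFAULT_TRUE_VOLUME,
                        M_list=DEFAULT_M_LIST,
                        n_datasets: int = 1000,
                        methods=BENCHMARK_METHODS,
                        seed: int = 0,
                        n_boot: int = 1000) -> list[BenchmarkResult]:
    """Benchmark estimator accuracy on synthetic induction-time series.

    For every (method, M) pair, ``n_datasets`` independent series are drawn
    from the generating truth and the estimator's mean absolute error for J
    and t_g is averaged over them.  Fits that fail (degenerate resamples,
    non-convergence) are excluded and counted.

    The closed-form estimators (``mle``, ``mle_bootstrap``) are fully
    vectorised; the least-squares routes (``direct``, ``bootstrap``) fit
    each series individually, and ``bootstrap`` (n_boot least-squares fits
    per series) is by far the slowest — shrink ``n_boot`` or ``n_datasets``
    for exploratory runs.
    """
    for m in methods:
        if m not in BENCHMARK_METHODS:
            raise ValueError(f"unknown method {m!r}; choose from {BENCHMARK_METHODS}")
    results = []
    root = np.random.SeedSequence(seed)
    for M, m_seed in zip(M_list, root.spawn(len(M_list))):
        # every method sees the same datasets at a given M
        times = _sample_time_matrix(np.random.default_rng(m_seed),
                                    true_params, volume_V, n_datasets, M)
        boot_seeds = np.random.SeedSequence(entropy=m_seed.entropy,
                                            spawn_key=(10_000,)).generate_state(n_datasets)
        for method in methods:
            J_hat = np.full(n_datasets, np.nan)
            tg_hat = np.full(n_datasets, np.nan)
            if method == "mle":
                tg_hat = times.min(axis=1)
                ssum = times.sum(axis=1) - M * tg_hat
                ok = ssum > 0
                J_hat[ok] = (M / ssum[ok]) / volume_V
                tg_hat[~ok] = np.nan
            elif method == "mle_bootstrap":
                for i in range(n_datasets):
                    rng_i = np.random.default_rng(int(boot_seeds[i]))
                    idx = rng_i.integers(0, M, size=(n_boot, M))
                    J_b, tg_b, ok_b = _mle_over_resamples(times[i], idx, volume_V)
                    if ok_b.any():
                        J_hat[i] = J_b[ok_b].mean()
                        tg_hat[i] = tg_b[ok_b].mean()
            else:  # direct or bootstrap: per-series least squares
                for i in range(n_datasets):
                    ds = InductionDataset(config_id=f"bench_{M}_{i}",
                                          times=tuple(times[i]),
                                          volume_V=volume_V)
                    try:
                        if method == "direct":
                            res = fit_direct(ds)
                        else:
                            res = bootstrap_fit(ds, n_boot=n_boot, base="direct",
                                                seed=int(boot_seeds[i]))
                        J_hat[i] = res.params.J
                        tg_hat[i] = res.params.t_g
                    except FitError:
                        pass
            ok = np.isfinite(J_hat) & np.isfinite(tg_hat) & (J_hat > 0)
            if not ok.any():
                raise FitError(f"all fits failed for method={method}, M={M}")
            results.append(BenchmarkResult(
                method=method, M=M,
                mae_J=float(np.mean(np.abs(J_hat[ok] - true_params.J))),
                mae_tg=float(np.mean(np.abs(tg_hat[ok] - true_params.t_g))),
                mae_log10_J=float(np.mean(np.abs(
                    np.log10(J_hat[ok]) - np.log10(true_params.J)))),
                n_datasets=int(ok.sum()), n_failed=int(n_datasets - ok.sum()),
                true_params=true_params, true_volume=volume_V))
    return results


def benchmark_frame(results: list[BenchmarkResult]) -> pd.DataFrame:
    """Tabulate benchmark results (one row per method and sample size)."""
    return pd.DataFrame([{
        "method": r.method, "M": r.M, "mae_J": r.mae_J, "mae_tg": r.mae_tg,
        "mae_log10_J": r.mae_log10_J, "n_datasets": r.n_datasets,
        "n_failed": r.n_failed} for r in results])


# ---------------------------------------------------------------------------
# CFD-like feature fabrication

# family mean = base scalar x coefficient x lognormal jitter(sigma);
# quantiles = family mean x {0.55, 0.8, 1.15}.  The quantile multipliers are
# deterministic so quantile columns are perfectly collinear with their family
# mean, forcing the correlation-based reduction to have work to do.
_QUANT_MULT = {"q25": 0.55, "q50": 0.8, "q75": 1.15}
_JITTER_SIGMA = 0.1


def _geometry_jitter(seed: int, config: VesselConfig, n: int) -> np.ndarray:
    """Per-geometry lognormal jitter, independent of impeller speed.

    Seeding from the geometry alone (not the speed) makes the fabricated
    fields exactly monotone in impeller speed within a vessel/impeller
    family, as they would be physically.
    """
    key = (f"{seed}|{config.scale_name}|{config.impeller_type}|"
           f"{config.working_volume:g}|{config.impeller_diameter:g}")
    h = int.from_bytes(hashlib.sha256(key.encode()).digest()[:8], "little")
    rng = np.random.default_rng(h)
    return np.exp(_JITTER_SIGMA * rng.standard_normal(n))


def generate_hydrodynamic_features(configs: list[VesselConfig],
                                   fluid: FluidProperties = IPA_SOLUTION,
                                   seed: int = 0) -> pd.DataFrame:
    """Fabricate a CFD-like feature table for a list of configurations.

    Family bases are built from classical scalars (tip speed, specific
    power, impeller speed) with impeller-type-dependent coefficients, then
    jittered; the result satisfies every schema invariant of a real table
    (positivity, quantile ordering, strong inter-feature correlation) but is
    a test fixture, not flow physics.

    Returns a DataFrame indexed by config_id with the 19 CFD columns plus
    the derived scalars (reynolds, tip_speed, specific_power).
    """
    rows = {}
    for cfg in configs:
        sc = derived_scalars(cfg, fluid)
        u_tip, eps = sc["tip_speed"], sc["specific_power"]
        n_s = cfg.speed_per_s
        jit = _geometry_jitter(seed, cfg, 7)
        # Metzner-Otto-style shear proportional to speed, with a geometry
        # factor so shear is not perfectly collinear with rpm across scales
        ks = 11.0 if cfg.impeller_type == "RC" else 13.0
        geom = (cfg.impeller_diameter / cfg.vessel_diameter) ** 0.5
        bases = {
            "sr": ks * n_s * geom * jit[0],
            "ep": eps / fluid.density_rho * jit[1],       # per unit mass
            "k": 0.1 * u_tip**2 * jit[2],
            "U": 0.3 * u_tip * jit[3],
        }
        row = {}
        for fam, base in bases.items():
            row[f"{fam}_mean"] = base
            for q, mult in _QUANT_MULT.items():
                row[f"{fam}_{q}"] = base * mult
        if cfg.impeller_type == "PBT":
            row["axial_mean"] = 0.12 * u_tip * jit[4]
            row["radial_mean"] = 0.08 * u_tip * jit[5]
        else:
            row["axial_mean"] = -0.03 * u_tip * jit[4]
            row["radial_mean"] = 0.20 * u_tip * jit[5]
        row["power_draw"] = eps * jit[6]
        row.update(sc)
        rows[cfg.config_id] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "config_id"
    order = list(CFD_FEATURE_COLUMNS) + ["reynolds", "tip_speed", "specific_power"]
    return validate_feature_frame(df[order].reset_index())


# ---------------------------------------------------------------------------
# End-to-end fabricated study

@dataclass(frozen=True)
class StudyNoise:
    """Noise specification for a fabricated study.

    ``n_times`` is the number of induction times sampled per configuration
    (default 80, the sample size generally considered adequate for fitting
    induction-time distributions); the sigma terms add configuration-level
    scatter on top of the ground-truth mapping before sampling.
    """

    n_times: int = 80
    sigma_log10_J: float = 0.03
    sigma_tg: float = 300.0


#: Ground-truth mapping defaults: log10(J) falls with volume and rises with
#: mean shear and dissipation; t_g falls with impeller speed and dissipation
#: (clipped at 600 s).  Shear/dissipation features enter standardized.
DEFAULT_MAPPING = {
    "log10_J": {"intercept": -3.26, "log10_volume_m3": -0.85,
                "z_sr_mean": 0.25, "z_ep_mean": 0.20},
    "t_g": {"intercept": 11_000.0, "z_impeller_speed": -3000.0,
            "z_ep_mean": -2000.0},
    "t_g_floor": 600.0,
}


@dataclass(frozen=True)
class SyntheticStudy:
    """A fully specified fabricated study with known ground truth."""

    configs: tuple
    features: pd.DataFrame = field(repr=False)
    true_mapping: dict = field(repr=False)
    true_params: dict = field(repr=False)  # config_id -> DistributionParams
    datasets: tuple = field(repr=False)
    z_stats: dict = field(repr=False)  # feature -> (mean, std) used by mapping
    seed: int = 0


def _default_configs(n_configs: int) -> list[VesselConfig]:
    base = vessel_configs()
    if n_configs == len(base):
        return base
    if n_configs < 4:
        raise ValueError("n_configs must be >= 4")
    train = [c for c in base if c.split_label == "training_validation"]
    test = [c for c in base if c.split_label == "testing"]
    if n_configs <= len(test) + 1:
        return (train[: n_configs - 1] + test[:1])
    if n_configs <= len(base):
        return train[: n_configs - len(test)] + test
    # extend by shifting impeller speeds of existing configurations
    extra = []
    i = 0
    while len(base) + len(extra) < n_configs:
        src = train[i % len(train)]
        bump = 1.1 + 0.05 * (i // len(train))
        extra.append(VesselConfig(
            scale_name=src.scale_name, vessel_diameter=src.vessel_diameter,
            liquid_height=src.liquid_height, impeller_type=src.impeller_type,
            impeller_diameter=src.impeller_diameter,
            impeller_speed=round(src.impeller_speed * bump, 1),
            working_volume=src.working_volume,
            split_label="training_validation"))
        i += 1
    return base + extra


def generate_study(n_configs: int = 17,
                   noise: StudyNoise = StudyNoise(),
                   seed: int = 0,
                   fluid: FluidProperties = IPA_SOLUTION,
                   mapping: dict | None = None) -> SyntheticStudy:
    """Fabricate a complete study: features, ground-truth (J, t_g), times.

    The configurations default to the 17 studied vessel/impeller/speed
    combinations (14 training/validation + 3 testing).  Features come from
    :func:`generate_hydrodynamic_features`; each configuration's true
    parameters follow the recorded linear mapping in (log-volume,
    standardized-feature) space, optionally perturbed by the noise spec; its
    induction times are then sampled exactly from the model CDF.
    """
    mapping = dict(DEFAULT_MAPPING if mapping is None else mapping)
    configs = _default_configs(n_configs)
    features = generate_hydrodynamic_features(configs, fluid=fluid, seed=seed)

    z_feats = sorted({k[2:] for tgt in ("log10_J", "t_g")
                      for k in mapping[tgt] if k.startswith("z_")})
    z_stats = {}
    z = {}
    for name in z_feats:
        if name == "impeller_speed":
            vals = np.array([c.impeller_speed for c in configs], dtype=float)
        else:
            vals = features[name].to_numpy(dtype=float)
        mu, sd = float(vals.mean()), float(vals.std(ddof=0))
        z_stats[name] = (mu, sd)
        z[name] = (vals - mu) / sd

    log10_V = np.log10([c.volume_m3 for c in configs])
    coef_J, coef_T = mapping["log10_J"], mapping["t_g"]
    log10_J = np.full(len(configs), coef_J["intercept"])
    log10_J += coef_J.get("log10_volume_m3", 0.0) * log10_V
    t_g = np.full(len(configs), coef_T["intercept"])
    for name in z_feats:
        log10_J += coef_J.get(f"z_{name}", 0.0) * z[name]
        t_g += coef_T.get(f"z_{name}", 0.0) * z[name]

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    log10_J = log10_J + noise.sigma_log10_J * rng.standard_normal(len(configs))
    t_g = t_g + noise.sigma_tg * rng.standard_normal(len(configs))
    t_g = np.maximum(t_g, mapping["t_g_floor"])

    true_params, datasets = {}, []
    child_seeds = np.random.SeedSequence(seed).spawn(len(configs) + 1)[1:]
    for i, cfg in enumerate(configs):
        p = DistributionParams(J=float(10.0 ** log10_J[i]), t_g=float(t_g[i]))
        true_params[cfg.config_id] = p
        ds = generate_induction_times(p, cfg.volume_m3, noise.n_times,
                                      child_seeds[i])
        datasets.append(InductionDataset(config_id=cfg.config_id,
                                         times=ds.times, volume_V=ds.volume_V))
    return SyntheticStudy(configs=tuple(configs), features=features,
                          true_mapping=mapping, true_params=true_params,
                          datasets=tuple(datasets), z_stats=z_stats, seed=seed)
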