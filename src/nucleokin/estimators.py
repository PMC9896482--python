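"""Estimators for the induction-time distribution parameters (J, t_g).

Four routes are provided, all returning an :class:`EstimatorResult`:

``fit_direct``
    Bounded nonlinear least squares of the model CDF against the observed
    cumulative probability at the ordered induction times.
``fit_mle``
    Closed-form maximum likelihood for the shifted exponential: the growth
    time estimate is the smallest observed induction time, and
    ``J*V = M / sum(t_i - min(t_i))``.
``bootstrap_fit``
    Resample the observations with replacement, re-estimate with either base
    method per resample, and report the mean and standard deviation of the
    parameter estimates across resamples.

The MLE is attractive for sparse series (few observations per configuration)
because it needs no optimizer and has no fitting convention; its price is a
systematic upward bias in both parameters (the sample minimum always
overestimates t_g).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .core_model import (
    DistributionParams,
    InductionDataset,
    empirical_cdf,
    model_cdf,
)

__all__ = [
    "EstimatorResult",
    "FitError",
    "DEFAULT_BOUNDS_J",
    "DEFAULT_BOUNDS_TG",
    "fit_direct",
    "fit_mle",
    "bootstrap_fit",
    "fit_quality",
]

#: Default box constraints for the direct fit, from initial fitting of the
#: paracetamol/IPA study data: J in #/(m^3 s), t_g in s.
DEFAULT_BOUNDS_J = (0.01, 20.0)
DEFAULT_BOUNDS_TG = (3000.0, 30000.0)


class FitError(RuntimeError):
    """Raised when an estimator cannot produce a usable fit.

    Carries the best candidate found (possibly None) and solver diagnostics.
    """

    def __init__(self, message: str, best_candidate=None, diagnostics=None):
        super().__init__(message)
        self.best_candidate = best_candidate
        self.diagnostics = diagnostics


@dataclass(frozen=True)
class EstimatorResult:
    """A fitted parameter pair plus fit quality and, if bootstrapped, spread.

    ``std_J``/``std_tg``/``n_boot`` are populated only by bootstrap methods;
    ``n_failed`` counts resamples dropped as degenerate or non-convergent.
    """

    params: DistributionParams
    method: str  # direct | mle | bootstrap | mle_bootstrap
    fit_rmse: float
    std_J: float | None = None
    std_tg: float | None = None
    n_boot: int | None = None
    n_failed: int = 0

    def __post_init__(self) -> None:
        if self.fit_rmse < 0:
            raise ValueError("fit_rmse must be >= 0")
        boot = self.method in ("bootstrap", "mle_bootstrap")
        if boot != (self.std_J is not None) or boot != (self.n_boot is not None):
            raise ValueError("std/n_boot fields must be present iff bootstrapped")


def fit_quality(dataset: InductionDataset, params: DistributionParams,
                convention: str = "i/M") -> float:
    """RMSE between observed cumulative probability and the model CDF.

    sqrt(mean over i of (P_empirical(t_i) - P_model(t_i))**2).
    """
    t, p_emp = empirical_cdf(dataset, convention)
    p_mod = model_cdf(t, params, dataset.volume_V)
    return float(np.sqrt(np.mean((p_emp - p_mod) ** 2)))


def fit_direct(dataset: InductionDataset,
               bounds_J: tuple[float, float] = DEFAULT_BOUNDS_J,
               bounds_tg: tuple[float, float] = DEFAULT_BOUNDS_TG,
               convention: str = "i/M") -> EstimatorResult:
    """Bounded nonlinear least-squares fit of the model CDF.

    Minimizes the sum of squared differences between the observed cumulative
    probabilities and the model CDF evaluated at the observed induction
    times.  The objective is flat in t_g above min(t_i) (the model then
    predicts P = 0 at every observation), so the solver is multi-started at
    t_g in {min t_i, 0.5 min t_i, lower bound} and the best converged
    candidate is kept.
    """
    if dataset.M < 2:
        raise FitError("direct fit needs at least 2 observations")
    for lo, hi in (bounds_J, bounds_tg):
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError("bounds must be finite with lower < upper")
    t, p_emp = empirical_cdf(dataset, convention)
    V = dataset.volume_V
    lo = np.array([bounds_J[0], bounds_tg[0]])
    hi = np.array([bounds_J[1], bounds_tg[1]])

    def residuals(x):
        p = -np.expm1(-x[0] * V * np.maximum(t - x[1], 0.0))
        return p - p_emp

    t_min = float(t[0])
    best = None
    diagnostics = []
    for tg0 in (t_min, 0.5 * t_min, bounds_tg[0]):
        tg0 = float(np.clip(tg0, *bounds_tg))
        # moment-style start for J: M / (V * sum(t - tg0)), clipped into box
        denom = float(np.sum(np.maximum(t - tg0, 0.0)))
        j0 = dataset.M / (V * denom) if denom > 0 else 1.0
        j0 = float(np.clip(j0, *bounds_J))
        sol = least_squares(residuals, x0=[j0, tg0], bounds=(lo, hi),
                            xtol=1e-12, ftol=1e-12, gtol=1e-12)
        diagnostics.append({"x0": (j0, tg0), "status": sol.status,
                            "cost": sol.cost})
        if sol.status > 0 and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise FitError("direct fit did not converge from any start",
                       best_candidate=None, diagnostics=diagnostics)
    J_hat, tg_hat = best.x
    params = DistributionParams(J=float(J_hat), t_g=float(tg_hat))
    rmse = float(np.sqrt(2.0 * best.cost / dataset.M))
    return EstimatorResult(params=params, method="direct", fit_rmse=rmse)


def fit_mle(dataset: InductionDataset,
            convention: str = "i/M") -> EstimatorResult:
    """Closed-form maximum likelihood estimate.

    The likelihood is nonzero only for t_g <= min(t_i) and increases in t_g
    there, so t_g_hat = min(t_i) exactly; maximizing the log-likelihood
    M*ln(JV) - JV*sum(t_i - t_g_hat) in JV gives
    J_hat = [M / sum(t_i - t_g_hat)] / V.
    """
    if dataset.M < 2:
        raise FitError("MLE needs at least 2 observations")
    t = dataset.times_array
    tg_hat = float(t[0])
    ssum = float(np.sum(t - tg_hat))
    if ssum <= 0:
        raise FitError("degenerate data: all induction times identical")
    J_hat = (dataset.M / ssum) / dataset.volume_V
    params = DistributionParams(J=J_hat, t_g=tg_hat)
    return EstimatorResult(params=params, method="mle",
                           fit_rmse=fit_quality(dataset, params, convention))


def _mle_over_resamples(t: np.ndarray, idx: np.ndarray, V: float):
    """Vectorised MLE over an (n_boot, M) index array; returns J, tg, ok."""
    samples = t[idx]
    tg = samples.min(axis=1)
    ssum = samples.sum(axis=1) - samples.shape[1] * tg
    ok = ssum > 0
    J = np.full(len(idx), np.nan)
    J[ok] = (samples.shape[1] / ssum[ok]) / V
    return J, tg, ok


def bootstrap_fit(dataset: InductionDataset, n_boot: int = 1000,
                  base: str = "direct", seed: int | None = None,
                  bounds_J: tuple[float, float] = DEFAULT_BOUNDS_J,
                  bounds_tg: tuple[float, float] = DEFAULT_BOUNDS_TG,
                  convention: str = "i/M") -> EstimatorResult:
    """Bootstrap the base estimator over resampled induction-time series.

    Each of ``n_boot`` resamples draws M observations with replacement; the
    base estimator (``direct`` or ``mle``) is applied to each, and the
    reported parameters are the mean of the per-resample estimates, with
    their standard deviations as uncertainty.  Degenerate resamples (all
    draws equal) and non-convergent fits are skipped and counted.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if base not in ("direct", "mle"):
        raise ValueError(f"base must be 'direct' or 'mle', got {base!r}")
    rng = np.random.default_rng(seed)
    t = dataset.times_array
    m = dataset.M
    idx = rng.integers(0, m, size=(n_boot, m))

    if base == "mle":
        J, tg, ok = _mle_over_resamples(t, idx, dataset.volume_V)
        J, tg = J[ok], tg[ok]
        n_failed = int(n_boot - ok.sum())
        method = "mle_bootstrap"
    else:
        Js, tgs, n_failed = [], [], 0
        for row in idx:
            sample = t[row]
            if sample.max() == sample.min():
                n_failed += 1
                continue
            try:
                res = fit_direct(
                    InductionDataset(config_id=dataset.config_id,
                                     times=tuple(sample),
                                     volume_V=dataset.volume_V),
                    bounds_J=bounds_J, bounds_tg=bounds_tg,
                    convention=convention)
            except FitError:
                n_failed += 1
                continue
            Js.append(res.params.J)
            tgs.append(res.params.t_g)
        J, tg = np.asarray(Js), np.asarray(tgs)
        method = "bootstrap"

    if len(J) == 0:
        raise FitError("all bootstrap resamples degenerate or failed")
    params = DistributionParams(J=float(np.mean(J)), t_g=float(np.mean(tg)))
    return EstimatorResult(
        params=params, method=method,
        fit_rmse=fit_quality(dataset, params, convention),
        std_J=float(np.std(J, ddof=0)), std_tg=float(np.std(tg, ddof=0)),
        n_boot=n_boot, n_failed=n_failed)


def fit(dataset: InductionDataset, method: str = "mle", *,
        n_boot: int = 1000, seed: int | None = None,
        bounds_J: tuple[float, float] = DEFAULT_BOUNDS_J,
        bounds_tg: tuple[float, float] = DEFAULT_BOUNDS_TG,
        convention: str = "i/M") -> EstimatorResult:
    """Dispatch to one of the four estimation routes by name."""
    if method == "direct":
        return fit_direct(dataset, bounds_J, bounds_tg, convention)
    if method == "mle":
        return fit_mle(dataset, convention)
    if method in ("bootstrap", "mle_bootstrap"):
        base = "mle" if method == "mle_bootstrap" else "direct"
        return bootstrap_fit(dataset, n_boot=n_boot, base=base, seed=seed,
                             bounds_J=bounds_J, bounds_tg=bounds_tg,
                             convention=convention)
    raise ValueError(f"unknown method {method!r}")
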