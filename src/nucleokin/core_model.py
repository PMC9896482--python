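"""Stochastic induction-time model for isothermal primary nucleation.

Under the single nucleus mechanism, nucleation in a stirred, supersaturated
solution is a stationary Poisson process with rate ``J * V`` (nucleation rate
per unit volume times solution volume).  A nucleus formed at time ``t_n``
needs a further growth time ``t_g`` before the crystal population becomes
detectable, so the observable induction time follows a shifted exponential
distribution::

    P(t) = 1 - exp(-J * V * (t - t_g))    for t >= t_g,  else 0

This module holds the model CDF, its inverse, the empirical cumulative
probability of an ordered induction-time series, and summary statistics.
Everything downstream (estimators, synthetic benchmarks, ensembles) is built
on these few functions.

Units are SI throughout: times in seconds, volumes in m**3, J in #/(m**3 s).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "StudyConditions",
    "DistributionParams",
    "InductionDataset",
    "VesselConfig",
    "CONVENTIONS",
    "model_cdf",
    "empirical_cdf",
    "summarize",
    "invert_cdf",
    "read_induction_csv",
    "write_induction_csv",
]

#: Supported plotting-position conventions for the empirical CDF.
#: "i/M" assigns the i-th ordered observation cumulative probability i/M;
#: "i/(M+1)" is the mean plotting position, which keeps P < 1 at the last
#: observation and is convenient for noise-free quantile constructions.
CONVENTIONS = ("i/M", "i/(M+1)")


@dataclass(frozen=True)
class StudyConditions:
    """Isothermal crystallization conditions of one induction-time series.

    ``supersaturation_S`` must be consistent with ``concentration_c /
    solubility_cstar`` to within 0.5% — it is stored (rather than always
    recomputed) because published studies round it.
    """

    temperature_C: float
    concentration_c: float  # g solute / kg solvent
    solubility_cstar: float  # g solute / kg solvent
    supersaturation_S: float  # dimensionless, c / c*

    def __post_init__(self) -> None:
        if self.concentration_c <= 0:
            raise ValueError("concentration_c must be positive")
        if self.solubility_cstar <= 0:
            raise ValueError("solubility_cstar must be positive")
        ratio = self.concentration_c / self.solubility_cstar
        if abs(self.supersaturation_S - ratio) > 0.005 * ratio:
            raise ValueError(
                f"supersaturation_S={self.supersaturation_S} inconsistent with "
                f"c/c*={ratio:.4f} (must agree within 0.5%)"
            )

    @classmethod
    def from_concentrations(
        cls, temperature_C: float, concentration_c: float, solubility_cstar: float
    ) -> "StudyConditions":
        return cls(
            temperature_C=temperature_C,
            concentration_c=concentration_c,
            solubility_cstar=solubility_cstar,
            supersaturation_S=concentration_c / solubility_cstar,
        )


@dataclass(frozen=True)
class DistributionParams:
    """Parameter pair of the induction-time distribution.

    Attributes
    ----------
    J : nucleation rate per unit volume, #/(m**3 s); strictly positive.
    t_g : growth time, s; the detection lag after the nucleation event.
    """

    J: float
    t_g: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.J) and self.J > 0):
            raise ValueError(f"J must be finite and > 0, got {self.J}")
        if not (np.isfinite(self.t_g) and self.t_g >= 0):
            raise ValueError(f"t_g must be finite and >= 0, got {self.t_g}")


@dataclass(frozen=True)
class InductionDataset:
    """One configuration's induction-time observations.

    ``times`` are stored sorted ascending; ``volume_V`` is the solution
    volume in m**3.  Censored (non-nucleated) runs are not representable:
    every observation must be a finite positive time.
    """

    config_id: str
    times: tuple = field(default=())
    volume_V: float = float("nan")

    def __post_init__(self) -> None:
        arr = np.asarray(self.times, dtype=float)
        if arr.size < 1:
            raise ValueError(f"dataset {self.config_id!r}: needs at least one time")
        if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
            raise ValueError(
                f"dataset {self.config_id!r}: times must be finite and > 0"
            )
        if not (np.isfinite(self.volume_V) and self.volume_V > 0):
            raise ValueError(f"dataset {self.config_id!r}: volume_V must be > 0")
        object.__setattr__(self, "times", tuple(np.sort(arr)))

    @property
    def M(self) -> int:
        return len(self.times)

    @property
    def times_array(self) -> np.ndarray:
        return np.asarray(self.times, dtype=float)


@dataclass(frozen=True)
class VesselConfig:
    """Geometry and operating point of one stirred-vessel configuration."""

    scale_name: str
    vessel_diameter: float  # mm
    liquid_height: float  # mm
    impeller_type: str  # "RC" (retreat curve) or "PBT" (pitched blade)
    impeller_diameter: float  # mm
    impeller_speed: float  # rpm
    working_volume: float  # mL
    split_label: str = "training_validation"  # or "testing"

    def __post_init__(self) -> None:
        for name in ("vessel_diameter", "liquid_height", "impeller_diameter",
                     "impeller_speed", "working_volume"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.impeller_diameter >= self.vessel_diameter:
            raise ValueError("impeller_diameter must be smaller than vessel_diameter")
        if self.impeller_type not in ("RC", "PBT"):
            raise ValueError(f"impeller_type must be RC or PBT, got {self.impeller_type!r}")
        if self.split_label not in ("training_validation", "testing"):
            raise ValueError(f"unknown split_label {self.split_label!r}")

    @property
    def config_id(self) -> str:
        return (f"{self.scale_name}_{self.working_volume:g}mL_"
                f"{self.impeller_type}_{self.impeller_speed:g}rpm")

    @property
    def volume_m3(self) -> float:
        return self.working_volume * 1e-6

    @property
    def speed_per_s(self) -> float:
        return self.impeller_speed / 60.0


def model_cdf(t, params: DistributionParams, volume_V: float):
    """Cumulative probability of detecting crystals by time ``t``.

    Vectorised over ``t``.  Returns 0 for ``t <= t_g`` and
    ``1 - exp(-J*V*(t - t_g))`` above the growth time.
    """
    if volume_V <= 0:
        raise ValueError("volume_V must be positive")
    t_arr = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t_arr)):
        raise ValueError("model_cdf: t must be finite")
    p = -np.expm1(-params.J * volume_V * np.maximum(t_arr - params.t_g, 0.0))
    return float(p) if np.isscalar(t) or t_arr.ndim == 0 else p


def invert_cdf(P, params: DistributionParams, volume_V: float):
    """Quantile function of the induction-time distribution.

    t = t_g - ln(1 - P) / (J * V), defined for 0 <= P < 1.
    """
    if volume_V <= 0:
        raise ValueError("volume_V must be positive")
    p_arr = np.asarray(P, dtype=float)
    if np.any(p_arr < 0) or np.any(p_arr >= 1):
        raise ValueError("invert_cdf: P must satisfy 0 <= P < 1")
    t = params.t_g - np.log1p(-p_arr) / (params.J * volume_V)
    return float(t) if np.isscalar(P) or p_arr.ndim == 0 else t


def empirical_cdf(dataset: InductionDataset, convention: str = "i/M"):
    """Observed cumulative probability at each ordered induction time.

    Returns ``(times, P)`` with times ascending and, under the default
    convention, ``P_i = i / M``.  Tied observations each keep their own rank,
    so the step function's value at a tied time is the largest rank there.
    """
    if convention not in CONVENTIONS:
        raise ValueError(f"convention must be one of {CONVENTIONS}, got {convention!r}")
    t = dataset.times_array
    m = dataset.M
    ranks = np.arange(1, m + 1, dtype=float)
    denom = m if convention == "i/M" else m + 1
    return t, ranks / denom


def summarize(dataset: InductionDataset) -> tuple[float, float]:
    """Mean and median induction time of a dataset.

    The mean is the arithmetic average; because experiments are not given
    infinite time to nucleate, the median is often the more robust summary
    when long induction times may be missing.
    """
    t = dataset.times_array
    return float(np.mean(t)), float(np.median(t))


# ---------------------------------------------------------------------------
# CSV I/O: long-format induction-time tables (config_id, time_s)

def write_induction_csv(datasets: Iterable[InductionDataset], path) -> None:
    """Write induction times as a long-format CSV with a volume column."""
    rows = []
    for ds in datasets:
        for t in ds.times:
            rows.append({"config_id": ds.config_id, "time_s": t,
                         "volume_m3": ds.volume_V})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_induction_csv(path, volumes: Mapping[str, float] | None = None
                       ) -> list[InductionDataset]:
    """Load induction-time datasets from a long-format CSV.

    The file must have columns ``config_id`` and ``time_s``; solution volumes
    are taken from a ``volume_m3`` column if present, otherwise from the
    ``volumes`` mapping (config_id -> m**3).
    """
    df = pd.read_csv(path)
    for col in ("config_id", "time_s"):
        if col not in df.columns:
            raise ValueError(f"induction CSV {path}: missing column {col!r}")
    if df["time_s"].isna().any() or (df["time_s"] <= 0).any():
        raise ValueError(f"induction CSV {path}: times must be present and > 0")
    out = []
    for cid, grp in df.groupby("config_id", sort=False):
        if "volume_m3" in df.columns:
            vols = grp["volume_m3"].unique()
            if len(vols) != 1:
                raise ValueError(f"config {cid!r}: inconsistent volume_m3 entries")
            vol = float(vols[0])
        elif volumes is not None and cid in volumes:
            vol = float(volumes[cid])
        else:
            raise ValueError(f"config {cid!r}: no volume available")
        out.append(InductionDataset(config_id=str(cid),
                                    times=tuple(grp["time_s"].astype(float)),
                                    volume_V=vol))
    return out
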