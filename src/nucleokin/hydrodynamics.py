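"""Classical stirred-tank scale-up quantities and CFD feature-table ingestion.

Three scalars commonly used to transfer stirred-vessel processes between
scales are computed from geometry and operating conditions:

* Reynolds number        Re    = rho * N * D**2 / mu
* impeller tip speed     u_tip = pi * N * D
* specific power input   eps   = N_p * rho * N**3 * D**5 / V

with N the impeller speed in rev/s, D the impeller diameter in m, and N_p
the impeller power number (1.3 for a pitched blade turbine, 1.07 for a
retreat curve impeller).  All public functions take SI units; rpm and mm are
converted at the I/O boundary.

The richer description of the flow field comes from CFD: per configuration,
19 summary fields (means and 25/50/75% quantiles of shear rate, turbulent
dissipation rate, turbulent kinetic energy and velocity magnitude, plus mean
axial/radial velocities and power draw).  ``load_cfd_features`` validates
such tables; the CFD ``power_draw`` column is kept distinct from the Eq-style
specific power computed here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as dc_fields

import numpy as np
import pandas as pd

from .core_model import VesselConfig

__all__ = [
    "FluidProperties",
    "HydrodynamicFeatures",
    "POWER_NUMBERS",
    "CFD_FEATURE_COLUMNS",
    "QUANTILE_FAMILIES",
    "DERIVED_COLUMNS",
    "IPA_SOLUTION",
    "reynolds",
    "tip_speed",
    "specific_power",
    "rpm_to_per_s",
    "derived_scalars",
    "load_cfd_features",
    "validate_feature_frame",
]

#: Impeller power numbers by type.
POWER_NUMBERS = {"PBT": 1.3, "RC": 1.07}

#: The 19 CFD summary fields, in canonical table order.
CFD_FEATURE_COLUMNS = (
    "sr_mean", "sr_q25", "sr_q50", "sr_q75",          # shear rate, 1/s
    "ep_mean", "ep_q25", "ep_q50", "ep_q75",          # turb. dissipation, m2/s3
    "k_mean", "k_q25", "k_q50", "k_q75",              # turb. kinetic energy, m2/s2
    "U_mean", "U_q25", "U_q50", "U_q75",              # velocity magnitude, m/s
    "axial_mean", "radial_mean",                      # signed velocities, m/s
    "power_draw",                                     # W/m3
)

#: Quantile families that must be internally ordered (q25 <= q50 <= q75).
QUANTILE_FAMILIES = ("sr", "ep", "k", "U")

#: Scalars derived from geometry/operation, appended to feature tables.
DERIVED_COLUMNS = ("reynolds", "tip_speed", "specific_power")

#: Columns allowed to be negative (signed mean velocity components).
_SIGNED = ("axial_mean", "radial_mean")


@dataclass(frozen=True)
class FluidProperties:
    """Density (kg/m**3) and dynamic viscosity (Pa s) of the working fluid."""

    density_rho: float
    viscosity_mu: float

    def __post_init__(self) -> None:
        if self.density_rho <= 0 or self.viscosity_mu <= 0:
            raise ValueError("density and viscosity must be positive")


#: Default preset for a paracetamol/isopropanol solution near 15 C.
IPA_SOLUTION = FluidProperties(density_rho=800.0, viscosity_mu=2.4e-3)


@dataclass(frozen=True)
class HydrodynamicFeatures:
    """The 19 CFD summary fields for one configuration plus derived scalars."""

    config_id: str
    sr_mean: float
    sr_q25: float
    sr_q50: float
    sr_q75: float
    ep_mean: float
    ep_q25: float
    ep_q50: float
    ep_q75: float
    k_mean: float
    k_q25: float
    k_q50: float
    k_q75: float
    U_mean: float
    U_q25: float
    U_q50: float
    U_q75: float
    axial_mean: float
    radial_mean: float
    power_draw: float
    reynolds: float
    tip_speed: float
    specific_power: float

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            if f.name == "config_id":
                continue
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ValueError(f"{self.config_id}: {f.name} must be finite")
            if f.name not in _SIGNED and v < 0:
                raise ValueError(f"{self.config_id}: {f.name} must be >= 0")
        for fam in QUANTILE_FAMILIES:
            q25, q50, q75 = (getattr(self, f"{fam}_q{q}") for q in (25, 50, 75))
            if not (q25 <= q50 <= q75):
                raise ValueError(
                    f"{self.config_id}: quantile ordering violated in family "
                    f"{fam!r} (q25={q25}, q50={q50}, q75={q75})")


def rpm_to_per_s(rpm: float) -> float:
    """Convert impeller speed from rev/min to rev/s."""
    return rpm / 60.0


def reynolds(fluid: FluidProperties, speed_N: float, impeller_D: float) -> float:
    """Impeller Reynolds number rho*N*D**2/mu (N in rev/s, D in m)."""
    if speed_N < 0 or impeller_D <= 0:
        raise ValueError("speed_N must be >= 0 and impeller_D > 0")
    return fluid.density_rho * speed_N * impeller_D**2 / fluid.viscosity_mu


def tip_speed(speed_N: float, impeller_D: float) -> float:
    """Impeller tip speed pi*N*D in m/s."""
    if speed_N < 0 or impeller_D < 0:
        raise ValueError("inputs must be nonnegative")
    return math.pi * speed_N * impeller_D


def specific_power(power_number_Np: float, fluid: FluidProperties,
                   speed_N: float, impeller_D: float, volume_V: float) -> float:
    """Specific power input N_p*rho*N**3*D**5/V in W per m**3 of liquid."""
    if volume_V <= 0:
        raise ValueError("volume_V must be positive")
    if power_number_Np <= 0 or speed_N < 0 or impeller_D <= 0:
        raise ValueError("N_p must be > 0, speed >= 0, D > 0")
    return power_number_Np * fluid.density_rho * speed_N**3 * impeller_D**5 / volume_V


def derived_scalars(config: VesselConfig,
                    fluid: FluidProperties = IPA_SOLUTION) -> dict[str, float]:
    """Re, u_tip and specific power for a vessel configuration (SI inside)."""
    n = rpm_to_per_s(config.impeller_speed)
    d = config.impeller_diameter * 1e-3
    return {
        "reynolds": reynolds(fluid, n, d),
        "tip_speed": tip_speed(n, d),
        "specific_power": specific_power(
            POWER_NUMBERS[config.impeller_type], fluid, n, d, config.volume_m3),
    }


def validate_feature_frame(df: pd.DataFrame, require_derived: bool = False
                           ) -> pd.DataFrame:
    """Validate a CFD feature table (one row per config_id).

    Checks presence of every CFD column, positivity where required, and
    quantile ordering per family; raises ValueError naming the offending
    column or row.  Returns the frame indexed by config_id.
    """
    if "config_id" in df.columns:
        df = df.set_index("config_id")
    if df.index.name != "config_id":
        raise ValueError("feature table must have a config_id column or index")
    required = CFD_FEATURE_COLUMNS + (DERIVED_COLUMNS if require_derived else ())
    for col in required:
        if col not in df.columns:
            raise ValueError(f"feature table missing column {col!r}")
    for col in required:
        vals = df[col].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"column {col!r} contains non-finite values")
        if col not in _SIGNED and np.any(vals < 0):
            bad = df.index[vals < 0][0]
            raise ValueError(f"column {col!r} negative for config {bad!r}")
    for fam in QUANTILE_FAMILIES:
        q25 = df[f"{fam}_q25"].to_numpy(dtype=float)
        q50 = df[f"{fam}_q50"].to_numpy(dtype=float)
        q75 = df[f"{fam}_q75"].to_numpy(dtype=float)
        bad = ~((q25 <= q50) & (q50 <= q75))
        if bad.any():
            row = df.index[bad][0]
            raise ValueError(
                f"quantile ordering violated in family {fam!r} for config {row!r}")
    return df


def load_cfd_features(path) -> list[HydrodynamicFeatures]:
    """Load and validate a CFD feature CSV into typed records.

    Derived scalars (Re, tip speed, specific power) must be present as their
    own columns; they are never inferred from, nor allowed to overwrite, the
    CFD columns.
    """
    df = validate_feature_frame(pd.read_csv(path), require_derived=True)
    out = []
    for cid, row in df.iterrows():
        kwargs = {c: float(row[c]) for c in CFD_FEATURE_COLUMNS + DERIVED_COLUMNS}
        out.append(HydrodynamicFeatures(config_id=str(cid), **kwargs))
    return out
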