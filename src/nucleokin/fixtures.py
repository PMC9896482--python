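"""Packaged study tables: vessel/impeller geometry and fitted kinetics.

Two CSV fixtures ship with the package:

* ``table1_vessels.csv`` — dimensions of the vessels and impellers studied
  (three scales: 100 mL, 1000 mL and 10 L; retreat-curve and pitched-blade
  impellers).
* ``table3_kinetics.csv`` — the 17 studied configurations with their fitted
  induction-time distribution parameters (J, t_g, to two significant
  figures), the number of induction-time observations M, the fit RMSE, and
  whether the configuration was used for ML training/validation or held out
  for testing.

Both are verified against embedded SHA-256 checksums at load time so that a
corrupted installation fails loudly rather than silently changing results.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

from .core_model import StudyConditions, VesselConfig

__all__ = ["load_fixtures", "vessel_configs", "config_id_for_row",
           "STUDY_CONDITIONS"]

#: Conditions of the induction-time study: paracetamol in isopropanol at
#: 15 C, c = 155.81 and c* = 97.38 g solute per kg solvent, i.e. a
#: supersaturation ratio c/c* of 1.6.
STUDY_CONDITIONS = StudyConditions.from_concentrations(
    temperature_C=15.0, concentration_c=155.81, solubility_cstar=97.38)

_CHECKSUMS = {
    "table1_vessels.csv":
        "5136d72778e7ab12aa2eca8100f2650afce65b1b00bd271b43abe5f61e062c97",
    "table3_kinetics.csv":
        "e31f46f927207af04b483fea13280bd27e7f5464cbf4e8697a711c00c1209dcd",
}

_VESSEL_SCALE = {"EasyMax": "100 mL", "OptiMax": "1000 mL", "Miniplant": "10 L"}
_SPLIT = {"training and validation": "training_validation", "testing": "testing"}


def _read_fixture(name: str) -> pd.DataFrame:
    ref = resources.files("nucleokin.data").joinpath(name)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise RuntimeError(f"fixture {name} checksum mismatch: {digest}")
    with ref.open("r") as fh:
        return pd.read_csv(fh)


def load_fixtures() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return the (vessel geometry, fitted kinetics) tables as DataFrames."""
    return _read_fixture("table1_vessels.csv"), _read_fixture("table3_kinetics.csv")


def config_id_for_row(row) -> str:
    return (f"{row['vessel']}_{row['volume_ml']:g}mL_"
            f"{row['impeller_type']}_{row['impeller_speed_rpm']:g}rpm")


def vessel_configs() -> list[VesselConfig]:
    """The 17 studied configurations as typed VesselConfig records."""
    vessels, kinetics = load_fixtures()
    geo = {(r["scale"], r["impeller_type"]): r for _, r in vessels.iterrows()}
    out = []
    for _, row in kinetics.iterrows():
        scale = _VESSEL_SCALE[row["vessel"]]
        key = (scale, row["impeller_type"])
        if key not in geo:
            # the 10 L vessel only carries an RC impeller in the geometry table
            raise ValueError(f"no geometry for scale {scale!r} with "
                             f"impeller {row['impeller_type']!r}")
        g = geo[key]
        out.append(VesselConfig(
            scale_name=row["vessel"],
            vessel_diameter=float(g["vessel_diameter_mm"]),
            liquid_height=float(g["liquid_height_mm"]),
            impeller_type=row["impeller_type"],
            impeller_diameter=float(g["impeller_diameter_mm"]),
            impeller_speed=float(row["impeller_speed_rpm"]),
            working_volume=float(row["volume_ml"]),
            split_label=_SPLIT[row["use_in_ml"]],
        ))
    return out
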