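"""Classical scale-up scalars and CFD-style feature tables.

Computes Reynolds number, impeller tip speed and specific power input for
the 17 packaged vessel/impeller configurations, then fabricates a CFD-like
feature table (19 flow-field summary columns with realistic collinearity)
for use by the correlation stage.
"""

import pandas as pd

from nucleokin import generate_hydrodynamic_features, vessel_configs
from nucleokin.hydrodynamics import derived_scalars

configs = vessel_configs()
scalars = pd.DataFrame({c.config_id: derived_scalars(c) for c in configs}).T
print(scalars.to_string(float_format="%.4g"))
print("\nreynolds is dimensionless, tip_speed in m/s, specific_power in "
      "W/m^3 of liquid.")

feats = generate_hydrodynamic_features(configs, seed=0)
print(f"\nfabricated CFD table: {feats.shape[0]} configurations x "
      f"{feats.shape[1]} columns")
print(feats[["sr_mean", "ep_mean", "U_mean", "power_draw"]].head(5)
      .to_string(float_format="%.4g"))
print("\nQuantile columns (q25/q50/q75 per family) are deliberately "
      "collinear with their family mean, as in real flow-field summaries.")
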