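"""Two-stage parameter estimation on a noisy synthetic leaf.

Generates a light response and a ci response with 5 % multiplicative
noise from known parameters, fits (Vcmax25, Jmax25) to the assimilation
data by RSS minimization, then recovers the emission coefficients (a, b)
from the linear regression of isoprene on the Rubisco electron demand Jv.
"""

from dataclasses import replace

import numpy as np

from isoflux import (
    DatasetDesign,
    EnergeticIsoParams,
    LeafEnvironment,
    PhotoParams,
    fit_ab_from_ci_response,
    fit_photo_params,
    generate_dataset,
)
from isoflux.io import records_from_table

truth_photo = PhotoParams(vcmax25=70.0, jmax25=130.0, rd25=0.5)
truth_iso = EnergeticIsoParams(a=0.3, b=0.1)
fixed = LeafEnvironment(par_absorbed=1000.0, t_leaf=30.0, ci=273.0)

light = DatasetDesign(kind="light_response", grid=np.linspace(150.0, 2000.0, 20),
                      photo=truth_photo, iso=truth_iso, fixed=fixed,
                      cv_a=0.05, cv_iso=0.05, seed=42)
ci = DatasetDesign(kind="ci_response", grid=np.linspace(60.0, 800.0, 20),
                   photo=truth_photo, iso=truth_iso, fixed=fixed,
                   cv_a=0.05, cv_iso=0.05, seed=43)

table_light, _ = generate_dataset(light)
table_ci, _ = generate_dataset(ci)

photo_fit = fit_photo_params(records_from_table(table_light), PhotoParams(rd25=0.5))
photo_hat = replace(PhotoParams(rd25=0.5),
                    vcmax25=photo_fit.estimates["vcmax25"],
                    jmax25=photo_fit.estimates["jmax25"])
ab_fit = fit_ab_from_ci_response(records_from_table(table_ci), photo_hat)

print(f"Vcmax25: true 70.0   fitted {photo_fit.estimates['vcmax25']:.2f}")
print(f"Jmax25:  true 130.0  fitted {photo_fit.estimates['jmax25']:.2f}")
print(f"a:       true 0.300  fitted {ab_fit.estimates['a']:.4f}")
print(f"b:       true 0.100  fitted {ab_fit.estimates['b']:.4f}")
print(f"regression r2 (isoprene vs Jv): {ab_fit.r_squared:.3f}")
print("With 5 % noise on both channels the two-stage procedure recovers all "
      "four parameters to within a few per cent.")
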