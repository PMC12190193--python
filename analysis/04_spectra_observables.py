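#!/usr/bin/env python
"""Extract order parameters and hydrophobicity from the CW spectra.

Runs the fluid-spectrum extraction (observed splittings -> order parameter
S) and the frozen-spectrum extraction (maximum splitting 2A_Z) on every
generated spectrum of the saturated and Chol-free mouse scenarios, and
compares against the generator's truth.  Chol orders the chains at all
depths (larger S) and makes the membrane center more hydrophobic
(smaller 2A_Z), with the hydrophobicity step between C9 and C10.

Writes results/order_parameters.csv and results/hydrophobicity.csv.
"""

from pathlib import Path

import pandas as pd

from lensepr.spectra import (
    default_tensor,
    extract_fluid_params,
    extract_two_az,
    order_parameter,
)
from lensepr.synth import ScenarioSpec, make_species_scenario

RESULTS = Path(__file__).resolve().parent.parent / "results"

if __name__ == "__main__":
    tensor = default_tensor()
    order_rows, az_rows = [], []
    for condition in ("no_chol", "saturated"):
        ds = make_species_scenario(ScenarioSpec("mouse", condition, seed=271))
        for lbl, sp in ds.fluid_spectra.items():
            p = extract_fluid_params(sp)
            truth = ds.truth["fluid_splittings"][lbl]
            s_fit = order_parameter(p.A_par_obs, p.A_perp_obs, tensor)
            s_true = order_parameter(truth["A_par"], truth["A_perp"], tensor)
            order_rows.append({"condition": condition, "label": lbl,
                               "A_par_obs": p.A_par_obs,
                               "A_perp_obs": p.A_perp_obs,
                               "S": s_fit, "S_true": s_true})
        for lbl, sp in ds.frozen_spectra.items():
            az_rows.append({"condition": condition, "label": lbl,
                            "two_Az": extract_two_az(sp),
                            "two_Az_true": ds.truth["two_Az"][lbl]})
    RESULTS.mkdir(exist_ok=True)
    df_s = pd.DataFrame(order_rows)
    df_az = pd.DataFrame(az_rows)
    df_s.to_csv(RESULTS / "order_parameters.csv", index=False)
    df_az.to_csv(RESULTS / "hydrophobicity.csv", index=False)
    print(df_s.round(3).to_string(index=False))
    print()
    print(df_az.round(2).to_string(index=False))
    print("\nChol raises S at every depth; 2A_Z drops between 9-SASL and "
          "10-PC in the saturated membrane (hydrophobicity steps up).")
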