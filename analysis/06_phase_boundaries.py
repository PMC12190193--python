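#!/usr/bin/env python
"""Predict cholesterol phase boundaries from phospholipid composition.

Applies the composition-weighted mixing model to the pure phospholipids
and to the mouse, pig and human lens-membrane compositions: the Chol
saturation limit (above which CBDs form) and the Chol solubility threshold
(above which Chol crystals form).  Despite drastically different PL
compositions, the predicted boundaries are nearly identical across species
— only PE (the minority lipid everywhere) pulls them down — which is the
model's explanation for lifespan-independent lens membrane homeostasis.

Writes results/phase_boundaries.csv.
"""

from pathlib import Path

import pandas as pd

from lensepr.composition import (
    default_phase_boundaries,
    load_species_presets,
    molpercent_to_ratio,
    normalize_composition,
    predict_cst,
    predict_saturation_limit,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"

if __name__ == "__main__":
    params = default_phase_boundaries()
    rows = []
    for pl in ("PC", "PE", "PS", "SM"):
        comp = normalize_composition({pl: 100}, species_label=f"pure {pl}")
        rows.append({"membrane": f"pure {pl}", "lifespan_years": None,
                     "sat_limit_molpct": predict_saturation_limit(comp, params),
                     "cst_molpct": predict_cst(comp, params)})
    for name, comp in load_species_presets().items():
        sat = predict_saturation_limit(comp, params)
        cst = predict_cst(comp, params)
        rows.append({"membrane": name, "lifespan_years": comp.lifespan_years,
                     "sat_limit_molpct": sat, "cst_molpct": cst,
                     "sat_limit_ratio": molpercent_to_ratio(sat),
                     "cst_ratio": molpercent_to_ratio(cst)})
    df = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "phase_boundaries.csv", index=False)
    print(df.round(3).to_string(index=False))
    species = df[df.lifespan_years.notna()]
    print(f"\ncross-species saturation-limit range: "
          f"{species.sat_limit_molpct.max() - species.sat_limit_molpct.min():.2f} "
          f"mol% over lifespans 3-70 y")
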