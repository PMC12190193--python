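{
  "comment": "Phospholipid headgroup compositions (mol%, four major PL classes) of eye-lens fiber-cell membranes for the three species models, with maximum lifespans. DHSM is folded into SM as total sphingolipid, so values need not sum to 100. Other species plotted in cross-species comparisons (rat 4, chick 6, sheep 20, cow 30 years) have no printed compositions and ship as labels only.",
  "presets": [
    {"species": "mouse", "lifespan_years": 3,  "molpercent": {"PC": 46, "PE": 17, "PS": 17, "SM": 15}},
    {"species": "pig",   "lifespan_years": 23, "molpercent": {"PC": 35, "PE": 12, "PS": 21, "SM": 29}},
    {"species": "human", "lifespan_years": 70, "molpercent": {"PC": 11, "PE": 15, "PS": 15, "SM": 66}}
  ],
  "other_lifespans_years": {"rat": 4, "chick": 6, "sheep": 20, "cow": 30}
}
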