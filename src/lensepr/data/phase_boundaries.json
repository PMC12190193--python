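{
  "comment": "Per-phospholipid cholesterol phase boundaries (mol% Chol) from an EPR/DSC fluid phase diagram of binary PL/Chol bilayers. sat_limit: Chol content above which cholesterol bilayer domains (CBDs) form; cst: cholesterol solubility threshold above which Chol crystals form. Literature CST values vary with preparation method; override this file to use different calibrations.",
  "sat_limit_per_pl": {"PC": 50.0, "PE": 33.0, "PS": 50.0, "SM": 50.0},
  "cst_per_pl": {"PC": 66.0, "PE": 50.0, "PS": 66.0, "SM": 66.0}
}
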