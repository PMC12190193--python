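{
  "comment": "Default principal values (gauss) of the 14N hyperfine tensor for doxyl-type nitroxides, typical spin-label literature values. Override for a different nitroxide or solvent calibration.",
  "A_xx": 6.3,
  "A_yy": 5.8,
  "A_zz": 33.6
}
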