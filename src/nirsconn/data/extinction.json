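{
  "comment": "Molar extinction coefficients for oxy- and deoxy-hemoglobin, mM^-1 cm^-1 (base-10), standard compendium values (Gratzer/Cope as distributed with HOMER).",
  "units": "mM^-1 cm^-1",
  "wavelengths_nm": [690, 830],
  "HbO": {"690": 0.276, "830": 0.974},
  "HbR": {"690": 2.05196, "830": 0.69304}
}
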