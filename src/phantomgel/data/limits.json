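{
  "schema": "phantomgel-concentration-limits-v1",
  "comment": "Default concentration bounds for recipe inversion. Agarose in percent w/v, salt in mM. Salt maxima are package defaults scaled to each salt's relaxivity so the attainable T1/T2 cloud covers sub-second tissue targets.",
  "agarose_max": 4.0,
  "salt_max": {
    "CuSO4": 10.0,
    "GdCl3-EDTA": 2.0,
    "MnCl2": 1.0,
    "NiCl2": 25.0
  }
}
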