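{
  "schema": "phantomgel-mixing-models-v1",
  "units": {"agarose": "percent w/v", "salt": "mM", "rate": "1/s", "field": "T"},
  "models": [
    {
      "salt": "CuSO4",
      "field_T": 0.0065,
      "t1_coefficients": [0.428, 1.07, 0.0, 1.71, 0.23, 1.25, 0.0, 0.0, 0.0],
      "t2_coefficients": [0.65, 7.68, 0.0366, 1.76, 0.194, 1.75, 0.0, 0.0, 0.0],
      "provenance": "published mixing-model coefficients, CuSO4, 0.0065 T"
    },
    {
      "salt": "CuSO4",
      "field_T": 0.064,
      "t1_coefficients": [0.412, 0.158, 0.0185, 1.52, 0.262, 0.83, 0.0, 0.0, 0.0],
      "t2_coefficients": [0.462, 7.03, 0.0, 1.52, 0.262, 2.88, 0.0, 0.0, 0.0],
      "provenance": "published mixing-model coefficients, CuSO4, 0.064 T"
    },
    {
      "salt": "CuSO4",
      "field_T": 0.55,
      "t1_coefficients": [0.391, 0.0324, 0.00651, 0.703, 0.144, 0.239, 0.0182, 0.000123, 0.0212],
      "t2_coefficients": [0.454, 7.47, 0.986, 0.703, 0.144, 0.0, 0.146, 0.0, 0.98],
      "provenance": "published mixing-model coefficients, CuSO4, 0.55 T"
    },
    {
      "salt": "GdCl3-EDTA",
      "field_T": 0.0065,
      "t1_coefficients": [0.428, 1.07, 0.0, 18.3, 0.0, 0.0, 0.0, 0.0, 0.0],
      "t2_coefficients": [0.65, 7.68, 0.0366, 18.3, 0.0, 0.0188, 0.0, 7.84, 0.0],
      "provenance": "published mixing-model coefficients, GdCl3-EDTA, 0.0065 T"
    },
    {
      "salt": "GdCl3-EDTA",
      "field_T": 0.064,
      "t1_coefficients": [0.412, 0.158, 0.0185, 15.6, 0.0, 0.0, 0.0, 0.0, 0.0],
      "t2_coefficients": [0.462, 7.03, 0.0, 15.6, 0.0, 7.56, 0.00658, 0.0, 0.0],
      "provenance": "published mixing-model coefficients, GdCl3-EDTA, 0.064 T"
    },
    {
      "salt": "GdCl3-EDTA",
      "field_T": 0.55,
      "t1_coefficients": [0.391, 0.0324, 0.00651, 8.5, 0.0, 0.0, 0.0, 0.0, 0.0],
      "t2_coefficients": [0.454, 7.47, 0.986, 8.5, 0.0, 16.2, 0.0, 0.0, 0.0],
      "provenance": "published mixing-model coefficients, GdCl3-EDTA, 0.55 T"
    },
    {
      "salt": "MnCl2",
      "field_T": 0.0065,
      "t1_coefficients": [0.428, 1.07, 0.0, 27.6, 0.0, 1.0, 1.0, 1.0, 1.0],
      "t2_coefficients": [0.65, 7.68, 0.0366, 42.7, 0.0, 1.0, 1.0, 1.0, 1.0],
      "provenance": "published mixing-model coefficients, MnCl2, 0.0065 T"
    },
    {
      "salt": "MnCl2",
      "field_T": 0.064,
      "t1_coefficients": [0.412, 0.158, 0.0185, 18.1, 0.0, 0.0, 0.0, 0.0, 0.0],
      "t2_coefficients": [0.462, 7.03, 0.0, 34.2, 0.0, 0.0, 0.0, 0.0, 0.0],
      "provenance": "published mixing-model coefficients, MnCl2, 0.064 T"
    },
    {
      "salt": "MnCl2",
      "field_T": 0.55,
      "t1_coefficients": [0.391, 0.0324, 0.00651, 8.59, 0.188, 2.96, 0.0183, 0.0, 0.0],
      "t2_coefficients": [0.454, 7.47, 0.986, 42.5, 0.0, 4.96, 0.0, 0.125, 0.0],
      "provenance": "published mixing-model coefficients, MnCl2, 0.55 T"
    },
    {
      "salt": "NiCl2",
      "field_T": 0.0065,
      "t1_coefficients": [0.428, 1.07, 0.0, 0.549, 0.00112, 0.0, 0.0, 0.0, 0.0],
      "t2_coefficients": [0.65, 7.68, 0.0366, 0.624, 0.000948, 0.0739, 0.0, 0.0, 0.0372],
      "provenance": "published mixing-model coefficients, NiCl2, 0.0065 T"
    },
    {
      "salt": "NiCl2",
      "field_T": 0.064,
      "t1_coefficients": [0.412, 0.158, 0.0185, 0.568, 0.0, 0.0, 0.0, 0.0, 0.0],
      "t2_coefficients": [0.462, 7.03, 0.0, 0.568, 0.0, 0.0, 0.0, 0.00504, 0.0],
      "provenance": "published mixing-model coefficients, NiCl2, 0.064 T"
    },
    {
      "salt": "NiCl2",
      "field_T": 0.55,
      "t1_coefficients": [0.391, 0.0324, 0.00651, 0.652, 0.000977, 0.0, 0.0, 0.0, 0.0],
      "t2_coefficients": [0.454, 7.47, 0.986, 0.652, 0.000977, 0.0, 0.0, 0.0525, 0.0],
      "provenance": "published mixing-model coefficients, NiCl2, 0.55 T"
    }
  ]
}
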