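{
  "kind": "lr_score",
  "coefficients": {
    "ITGB4": -0.263,
    "SDC1": 0.177,
    "GPC2": -0.13,
    "TLR6": -0.0838,
    "CEACAM1": -0.0607,
    "JAG1": 0.058,
    "NOTCH3": 0.0501,
    "LDLR": -0.0469,
    "ACVR2B": -0.0511,
    "SLIT2": -0.0191,
    "TIE1": -0.00592
  },
  "provenance": "paper",
  "expression_scale": "unspecified"
}
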