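{
  "description": "Endogenous presynaptic Ca2+ buffer set (literature-sourced editable defaults; single-site approximations). Units: total uM, kon 1/(uM*ms), koff 1/ms, D um^2/ms.",
  "buffers": [
    {"name": "calmodulin", "total": 100.0, "kon": 0.1, "koff": 10.0, "D": 0.020},
    {"name": "calbindin_d28k", "total": 40.0, "kon": 0.075, "koff": 0.0295, "D": 0.020},
    {"name": "atp", "total": 400.0, "kon": 0.5, "koff": 100.0, "D": 0.220}
  ]
}
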