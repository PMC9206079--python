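{
  "description": "Intracellular pipette buffer set (whole-cell dialysis; literature-sourced editable defaults). Units: total uM, kon 1/(uM*ms), koff 1/ms, D um^2/ms.",
  "buffers": [
    {"name": "egta", "total": 1000.0, "kon": 0.0027, "koff": 0.0005, "D": 0.220},
    {"name": "atp", "total": 400.0, "kon": 0.5, "koff": 100.0, "D": 0.220}
  ]
}
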