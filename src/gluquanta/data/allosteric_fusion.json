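{
  "description": "Phenomenological allosteric model of Ca2+-triggered vesicle fusion: five sequential Ca2+ binding steps with cooperativity factor b on unbinding and fusion rate l_plus * f^n from the n-bound state. Published parameter values of the cited calyx-of-Held model. Units: kon 1/(uM*ms), koff 1/ms, l_plus 1/ms.",
  "kon": 0.1,
  "koff": 4.0,
  "b": 0.5,
  "l_plus": 2e-7,
  "f": 31.3,
  "n_sites": 5
}
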