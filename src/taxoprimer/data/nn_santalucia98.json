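{
  "comment": "Unified oligonucleotide nearest-neighbor parameters (SantaLucia, PNAS 1998). Enthalpy kcal/mol, entropy cal/(mol K). Stacks keyed by the 5'->3' top-strand dinucleotide; the ten unique stacks are listed, reverse-complement lookups resolve the rest. Initiation terms are per duplex end by terminal pair.",
  "stacks": {
    "AA": {"dh": -7.9, "ds": -22.2},
    "AT": {"dh": -7.2, "ds": -20.4},
    "TA": {"dh": -7.2, "ds": -21.3},
    "CA": {"dh": -8.5, "ds": -22.7},
    "GT": {"dh": -8.4, "ds": -22.4},
    "CT": {"dh": -7.8, "ds": -21.0},
    "GA": {"dh": -8.2, "ds": -22.2},
    "CG": {"dh": -10.6, "ds": -27.2},
    "GC": {"dh": -9.8, "ds": -24.4},
    "GG": {"dh": -8.0, "ds": -19.9}
  },
  "initiation": {
    "GC": {"dh": 0.1, "ds": -2.8},
    "AT": {"dh": 2.3, "ds": 4.1}
  }
}
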