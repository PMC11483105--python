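{
  "superficial": ["PRG4", "IGFBP5", "CHI3L1", "OGN"],
  "deep": ["COL10A1", "IBSP", "CLEC3A", "F13A1"]
}
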