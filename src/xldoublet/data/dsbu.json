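{
  "name": "DSBU",
  "spacer": {"C": 9, "H": 12, "N": 2, "O": 3},
  "stubs": {
    "Bu": {"C": 4, "H": 7, "N": 1, "O": 1},
    "BuUr": {"C": 5, "H": 5, "N": 1, "O": 2}
  },
  "doublet_pair": ["Bu", "BuUr"],
  "complement_pairs": [["Bu", "BuUr"]],
  "hydrogen_shifts": [0]
}
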