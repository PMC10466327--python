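{
  "name": "DSSO",
  "spacer": {"C": 6, "H": 6, "O": 3, "S": 1},
  "stubs": {
    "A": {"C": 3, "H": 2, "O": 1},
    "T": {"C": 3, "H": 2, "O": 1, "S": 1},
    "S": {"C": 3, "H": 4, "O": 2, "S": 1}
  },
  "doublet_pair": ["A", "T"],
  "complement_pairs": [["A", "S"]],
  "hydrogen_shifts": [0]
}
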