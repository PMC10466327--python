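{
  "name": "UCCL",
  "spacer": {"C": 12, "H": 12, "O": 2, "S": 2},
  "stubs": {
    "A": {"C": 2, "H": 2, "O": 1},
    "B": {"C": 2, "H": 2, "O": 1, "S": 1},
    "C": {"C": 10, "H": 10, "O": 1, "S": 1},
    "D": {"C": 10, "H": 10, "O": 1, "S": 2}
  },
  "doublet_pair": ["B", "C"],
  "complement_pairs": [["A", "D"], ["B", "C"]],
  "hydrogen_shifts": [0, 1, 2]
}
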