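{
  "FC5": ["FC", 5], "FC3": ["FC", 3], "FC1": ["FC", 1],
  "FC2": ["FC", 2], "FC4": ["FC", 4], "FC6": ["FC", 6],
  "C5": ["C", 5], "C3": ["C", 3], "C1": ["C", 1],
  "C2": ["C", 2], "C4": ["C", 4], "C6": ["C", 6],
  "CP5": ["CP", 5], "CP3": ["CP", 3], "CP1": ["CP", 1],
  "CP2": ["CP", 2], "CP4": ["CP", 4], "CP6": ["CP", 6],
  "P5": ["P", 5], "P3": ["P", 3], "P1": ["P", 1],
  "P2": ["P", 2], "P4": ["P", 4], "P6": ["P", 6]
}
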