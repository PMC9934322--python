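{
  "p1": 0.563,
  "p2": 1.0,
  "p3": 0.666,
  "t1": 0.94,
  "t2": 0.1,
  "t3": 0.0,
  "t4": 0.004,
  "alpha": 0.1
}
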