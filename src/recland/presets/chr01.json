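{
  "p1": 0.529,
  "p2": 1.0,
  "p3": 1.0,
  "t1": 0.97,
  "t2": 0.9,
  "t3": 0.0,
  "t4": 0.002,
  "alpha": 0.1
}
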