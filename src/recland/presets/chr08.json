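{
  "p1": 0.453,
  "p2": 0.0,
  "p3": 0.1,
  "t1": 0.94,
  "t2": 1.0,
  "t3": 0.1,
  "t4": 0.004,
  "alpha": 0.1
}
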