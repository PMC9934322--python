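{
  "p1": 0.568,
  "p2": 0.102,
  "p3": 0.5,
  "t1": 0.95,
  "t2": 1.0,
  "t3": 0.1,
  "t4": 0.001,
  "alpha": 0.1
}
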