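{
  "PRM-VT": {"a": 3.4140, "b": -2.1981e-2, "c": 3.5557e-5, "R2": 0.954},
  "PRSV-VT": {"a": 1.3550, "b": -8.9000e-3, "c": 1.4854e-5, "R2": 0.964},
  "SAFT": {"a": 0.5930, "b": -4.0773e-3, "c": 6.9106e-6, "R2": 0.976}
}
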