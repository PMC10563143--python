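{
  "input": {"random_bytes": 120},
  "pipeline": {"family": "rs", "inner": ["1,55", "9,47"]},
  "fault_model": {"kind": "iid", "rate": [0.01, 0.1]},
  "copy_model": {"kind": "constant", "depth": [3, 9, 15]},
  "iterations": 100,
  "master_seed": 17
}
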