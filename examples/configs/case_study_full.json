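[
  {
    "input": {"random_bytes": 2780},
    "pipeline": {
      "family": "rs",
      "inner": ["1,55", "9,47", "14,42", "28,28"]
    },
    "fault_model": {"spec": ["iid:0.01", "iid:0.05", "iid:0.1", "contextual:nanopore"]},
    "copy_model": {"kind": "constant", "depth": [3, 5, 10, 15, 20, 25, 30]},
    "iterations": 1024,
    "master_seed": 2023
  },
  {
    "input": {"random_bytes": 2780},
    "pipeline": {
      "family": "hedges",
      "inner": ["0.167,4", "0.25,9", "0.5,24", "0.75,39"]
    },
    "fault_model": {"spec": ["iid:0.01", "iid:0.05", "iid:0.1", "contextual:nanopore"]},
    "copy_model": {"kind": "constant", "depth": 1},
    "iterations": 1024,
    "master_seed": 2023
  },
  {
    "input": {"random_bytes": 2780},
    "pipeline": {
      "family": "hedges_msa",
      "inner": ["0.167,4", "0.25,9", "0.5,24", "0.75,39"]
    },
    "fault_model": {"spec": ["iid:0.01", "iid:0.05", "iid:0.1", "contextual:nanopore"]},
    "copy_model": {"kind": "constant", "depth": [3, 5, 10, 15, 20, 25, 30]},
    "iterations": 1024,
    "master_seed": 2023
  }
]
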