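[
  {
    "name": "control",
    "steps": 100,
    "overrides": {"IGF1": 20, "INS": 20},
    "kernel": {"mode": "indicator", "activity_threshold": 0}
  },
  {
    "name": "IGF1R-KD",
    "steps": 100,
    "overrides": {"IGF1R": 0, "IGF1": 0, "INS": 20},
    "kernel": {"mode": "indicator", "activity_threshold": 0}
  },
  {
    "name": "INSR-KD",
    "steps": 100,
    "overrides": {"INSR": 0, "INS": 0, "IGF1": 20},
    "kernel": {"mode": "indicator", "activity_threshold": 0}
  }
]
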