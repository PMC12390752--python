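{
  "name": "phrase",
  "description": "Three-word phrase stored across three carriers and accessed with no key, the admin key, and the matched user key; one yield-table row per word.",
  "scaffold": {"seed": 1942, "length": 7249},
  "designs": [{"design_id": "DDC-1", "breakpoint": 0}],
  "params": {},
  "n_structures": 1000,
  "seed": 202,
  "conditions": [
    {"design": "DDC-1", "message": "DNA NANO TECH", "key": "none"},
    {"design": "DDC-1", "message": "DNA NANO TECH", "key": "admin"},
    {"design": "DDC-1", "message": "DNA NANO TECH", "key": "user:DDC-1"}
  ]
}
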