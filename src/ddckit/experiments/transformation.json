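{
  "name": "transformation",
  "description": "Keyed conformational transformation of a marker-only carrier: trigger-free retention vs admin (polymerase) and matched user (strand-set) unlocking.",
  "scaffold": {"seed": 1942, "length": 7249},
  "designs": [{"design_id": "DDC-1", "breakpoint": 0}],
  "params": {},
  "n_structures": 1500,
  "seed": 101,
  "conditions": [
    {"design": "DDC-1", "pattern": [[0,0,0,0,0],[0,0,0,0,0],[0,0,0,0,0],[0,0,0,0,0],[0,0,0,0,0]], "key": "none", "label": "DDC-1/markers/none"},
    {"design": "DDC-1", "pattern": [[0,0,0,0,0],[0,0,0,0,0],[0,0,0,0,0],[0,0,0,0,0],[0,0,0,0,0]], "key": "admin", "label": "DDC-1/markers/admin"},
    {"design": "DDC-1", "pattern": [[0,0,0,0,0],[0,0,0,0,0],[0,0,0,0,0],[0,0,0,0,0],[0,0,0,0,0]], "key": "user:DDC-1", "label": "DDC-1/markers/user"}
  ]
}
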