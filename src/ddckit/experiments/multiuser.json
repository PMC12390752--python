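{
  "name": "multiuser",
  "description": "Two-user permission matrix: text payload on DDC-1, icon payload on DDC-2; admin accesses both, each user key only its own carrier.",
  "scaffold": {"seed": 1942, "length": 7249},
  "designs": [
    {"design_id": "DDC-1", "breakpoint": 0},
    {"design_id": "DDC-2", "breakpoint": 3624}
  ],
  "params": {},
  "n_structures": 1000,
  "seed": 303,
  "conditions": [
    {"design": "DDC-1", "message": "PEACE", "key": "admin"},
    {"design": "DDC-2", "pattern": [[0,1,0,1,0],[1,1,1,1,1],[1,1,1,1,1],[0,1,1,1,0],[0,0,1,0,0]], "key": "admin", "label": "DDC-2/heart/admin"},
    {"design": "DDC-1", "message": "PEACE", "key": "user:DDC-1"},
    {"design": "DDC-2", "pattern": [[0,1,0,1,0],[1,1,1,1,1],[1,1,1,1,1],[0,1,1,1,0],[0,0,1,0,0]], "key": "user:DDC-2", "label": "DDC-2/heart/user2"},
    {"design": "DDC-1", "message": "PEACE", "key": "user:DDC-2"},
    {"design": "DDC-2", "pattern": [[0,1,0,1,0],[1,1,1,1,1],[1,1,1,1,1],[0,1,1,1,0],[0,0,1,0,0]], "key": "user:DDC-1", "label": "DDC-2/heart/user1"}
  ]
}
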