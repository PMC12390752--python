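{
 "design_id": "DDC-2",
 "grid_rows": 5,
 "grid_cols": 5,
 "address_rows": 1,
 "n_edge_staples": 13,
 "overhang_domain_ids": [
  "dom1",
  "dom2",
  "dom3",
  "dom4",
  "dom5",
  "dom6",
  "dom7",
  "dom1",
  "dom2",
  "dom3",
  "dom4",
  "dom5",
  "dom6"
 ],
 "gap_region_seqs": [
  "GCCAAATACCTGGCGC",
  "TCAGAGTAAAGTTTGG"
 ],
 "overhang_domain_seqs": {
  "dom1": "CAACTTACTCATGAT",
  "dom2": "TTCTGATGGACGCTG",
  "dom3": "ACCCCGGGCGAAAAG",
  "dom4": "GGTCAGATGTGCCGC",
  "dom5": "GTTTTGCCAAAGACA",
  "dom6": "GCAGACTTATTCATA",
  "dom7": "CTGGCAATCAAGCCG"
 },
 "n_gap_regions": 2,
 "scaffold_id": "synM13-7249-s1942",
 "breakpoint": 3624,
 "pitch_off": [
  6.0,
  6.0
 ],
 "pitch_on": [
  6.0,
  12.0
 ],
 "marker_sites": [
  [
   2,
   -2
  ],
  [
   4,
   -2
  ]
 ],
 "schema_version": 1
}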