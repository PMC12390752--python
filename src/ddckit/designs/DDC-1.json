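{
 "design_id": "DDC-1",
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
  "CCCACTTTAAACAGTT",
  "AGACGAAAAGCACCGG"
 ],
 "overhang_domain_seqs": {
  "dom1": "TATTTCAGGGGCGCC",
  "dom2": "TTGTGGGACGCTTTT",
  "dom3": "CGGACATCGGGTAGT",
  "dom4": "TTCTCACAACCATTG",
  "dom5": "CTTGGAACTAGGCCG",
  "dom6": "TTCTGTTGTCTCTTC",
  "dom7": "TCGACCCTAAACGAC"
 },
 "n_gap_regions": 2,
 "scaffold_id": "synM13-7249-s1942",
 "breakpoint": 0,
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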