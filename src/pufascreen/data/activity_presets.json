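{
  "bdelloid_characterized": {
    "description": "Characterized activity set: dual d12/d15 methyl-end desaturases, d6 and d5 front-end desaturases, elongase on C18 and C20 substrates.",
    "activities": [
      {"kind": "methyl_end_desaturation", "delta": 12},
      {"kind": "methyl_end_desaturation", "delta": 15},
      {"kind": "front_end_desaturation", "delta": 6},
      {"kind": "front_end_desaturation", "delta": 5},
      {"kind": "elongation", "substrate_carbons": [18, 20]}
    ]
  },
  "elovl25": {
    "description": "Elongase alone, C18 and C20 substrates.",
    "activities": [
      {"kind": "elongation", "substrate_carbons": [18, 20]}
    ]
  },
  "fed_d5": {
    "description": "Front-end desaturase, d5 activity.",
    "activities": [
      {"kind": "front_end_desaturation", "delta": 5}
    ]
  },
  "fed_d6": {
    "description": "Front-end desaturase, d6 activity.",
    "activities": [
      {"kind": "front_end_desaturation", "delta": 6}
    ]
  },
  "wx": {
    "description": "Methyl-end desaturase with dual d12/d15 activities.",
    "activities": [
      {"kind": "methyl_end_desaturation", "delta": 12},
      {"kind": "methyl_end_desaturation", "delta": 15}
    ]
  }
}
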