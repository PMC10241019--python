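{
  "description": "Tissue weighting factors. icrp26_ede: the older weights used for the effective dose equivalent; icrp60_ed: the newer weights used for the effective dose. 'remainder' is split uniformly over table organs without an explicit weight. Keys are canonical organ names.",
  "icrp26_ede": {
    "gonads": 0.25,
    "breast": 0.15,
    "marrow": 0.12,
    "lung": 0.12,
    "thyroid": 0.03,
    "bone_surface": 0.03,
    "remainder": 0.30
  },
  "icrp60_ed": {
    "gonads": 0.20,
    "marrow": 0.12,
    "colon": 0.12,
    "lung": 0.12,
    "stomach": 0.12,
    "bladder": 0.05,
    "breast": 0.05,
    "liver": 0.05,
    "esophagus": 0.05,
    "thyroid": 0.05,
    "skin": 0.01,
    "bone_surface": 0.01,
    "remainder": 0.05
  }
}
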