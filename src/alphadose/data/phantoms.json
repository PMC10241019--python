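{
  "description": "Default phantoms: an ICRP-89-style adult female organ-mass table (60 kg) and a 25 g laboratory mouse. Masses in grams. Under relative-organ-mass scaling the organ masses cancel algebraically; only the body-mass ratio affects per-gram concentrations, so these tables chiefly document which organs are mapped and support %IA-per-organ reporting.",
  "mouse": {
    "species": "mouse",
    "body_mass_g": 25.0,
    "organ_masses_g": {
      "blood": 1.7,
      "bladder": 0.1,
      "bone": 2.1,
      "brain": 0.4,
      "femur": 0.08,
      "heart": 0.15,
      "kidney": 0.33,
      "liver": 1.3,
      "lung": 0.15,
      "marrow": 0.22,
      "muscle": 9.5,
      "ovaries": 0.01,
      "pancreas": 0.1,
      "skin": 3.0,
      "spleen": 0.1,
      "stomach": 0.25,
      "thymus": 0.03,
      "thyroid": 0.003,
      "uterus": 0.03
    }
  },
  "human_female": {
    "species": "human_female",
    "body_mass_g": 60000.0,
    "organ_masses_g": {
      "blood": 4100.0,
      "bladder": 40.0,
      "bone": 7800.0,
      "brain": 1300.0,
      "femur": 1000.0,
      "heart": 250.0,
      "kidney": 275.0,
      "liver": 1400.0,
      "lung": 950.0,
      "marrow": 900.0,
      "muscle": 17500.0,
      "ovaries": 11.0,
      "pancreas": 120.0,
      "skin": 2300.0,
      "spleen": 130.0,
      "stomach": 140.0,
      "thymus": 20.0,
      "thyroid": 17.0,
      "uterus": 80.0
    }
  }
}
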