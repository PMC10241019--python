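{
  "description": "225Ac serial decay chain through stable 209Bi. Half-lives and mean alpha energies per decay follow ICRP Publication 107 nuclear decay data; the 213Bi branch split uses the 2%/98% alpha/beta weighting. mean_alpha_energy_mev is the mean alpha energy emitted per decay of that nuclide (already branch-averaged for 213Bi); 0 for pure beta steps.",
  "parent": "225Ac",
  "nuclides": [
    {
      "name": "225Ac",
      "half_life_s": 857088.0,
      "mean_alpha_energy_mev": 5.7866,
      "branches": [["221Fr", 1.0, "alpha"]]
    },
    {
      "name": "221Fr",
      "half_life_s": 294.0,
      "mean_alpha_energy_mev": 6.303,
      "branches": [["217At", 1.0, "alpha"]]
    },
    {
      "name": "217At",
      "half_life_s": 0.0323,
      "mean_alpha_energy_mev": 7.0669,
      "branches": [["213Bi", 1.0, "alpha"]]
    },
    {
      "name": "213Bi",
      "half_life_s": 2735.4,
      "mean_alpha_energy_mev": 0.117384,
      "branches": [["213Po", 0.98, "beta"], ["209Tl", 0.02, "alpha"]]
    },
    {
      "name": "213Po",
      "half_life_s": 4.2e-06,
      "mean_alpha_energy_mev": 8.3759,
      "branches": [["209Pb", 1.0, "alpha"]]
    },
    {
      "name": "209Tl",
      "half_life_s": 132.0,
      "mean_alpha_energy_mev": 0.0,
      "branches": [["209Pb", 1.0, "beta"]]
    },
    {
      "name": "209Pb",
      "half_life_s": 11710.8,
      "mean_alpha_energy_mev": 0.0,
      "branches": [["209Bi", 1.0, "beta"]]
    },
    {
      "name": "209Bi",
      "half_life_s": null,
      "mean_alpha_energy_mev": 0.0,
      "branches": []
    }
  ]
}
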