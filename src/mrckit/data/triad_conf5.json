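{
  "format": "mrckit-fixture-1",
  "name": "triad_conf5",
  "description": "Four-state carotenoid-porphyrin-C60 triad in THF, conformation #5: printed energy minima, interstate couplings, energy corrections, and pairwise reorganization energies. The bath block is a SYNTHETIC Debye stand-in (the all-atom spectral densities are not packaged).",
  "states": ["pipi*", "CT1", "CT2", "G"],
  "ground_state": 3,
  "epsilons": {"unit": "eV", "values": [0.0, -0.758, -1.128, 0.0]},
  "energy_corrections": {"unit": "eV", "values": [1.551, -0.697, -0.650, 0.0]},
  "gammas": {"unit": "eV", "pairs": {"12": 0.081, "13": 0.0041, "23": -0.0032}},
  "reorg": {"unit": "kcal/mol", "pairs": {"12": 6.464, "13": 18.68, "14": 20.22, "23": 0.3096, "24": 7.920, "34": 18.95}},
  "bath": {"synthetic": true, "kind": "debye", "omega_c_cm1": 200.0, "omega_max_cm1": 1500.0, "n_modes": 200}
}
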