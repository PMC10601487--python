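{
  "format": "mrckit-fixture-1",
  "name": "triad_conf3",
  "description": "Four-state carotenoid-porphyrin-C60 triad in THF, conformation #3: printed energy minima, interstate couplings, energy corrections, and pairwise reorganization energies. The bath block is a SYNTHETIC Debye stand-in (the all-atom spectral densities are not packaged).",
  "states": ["pipi*", "CT1", "CT2", "G"],
  "ground_state": 3,
  "epsilons": {"unit": "eV", "values": [0.0, -0.828, -0.640, 0.0]},
  "energy_corrections": {"unit": "eV", "values": [0.728, -2.103, -2.131, 0.0]},
  "gammas": {"unit": "eV", "pairs": {"12": -0.015, "13": 0.0072, "23": -0.029}},
  "reorg": {"unit": "kcal/mol", "pairs": {"12": 7.880, "13": 11.39, "14": 0.9202, "23": 3.546, "24": 21.23, "34": 26.42}},
  "bath": {"synthetic": true, "kind": "debye", "omega_c_cm1": 200.0, "omega_max_cm1": 1500.0, "n_modes": 200}
}
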