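{
  "name": "erlotinib (in-silico predicted)",
  "molecular_weight": 393.45,
  "logP": 3.13,
  "pKa_base": 4.46,
  "intrinsic_solubility": 0.078,
  "solubility_factor": 334.4,
  "reference_solubility_pH2": 22.44,
  "fassif_solubility": 0.003,
  "fessif_solubility": 0.117,
  "solubilization_ratio": 10300.0,
  "effective_permeability": 0.00027,
  "fraction_unbound": 0.0457,
  "blood_plasma_ratio": 0.71,
  "hepatic_clearance": 40.0,
  "particle_radius": 25.0,
  "mean_precipitation_time": 900.0,
  "oral_bioavailability_F": 0.60
}
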