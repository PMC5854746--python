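{
  "name": "erlotinib",
  "molecular_weight": 393.45,
  "logP": 2.7,
  "pKa_base": 5.4,
  "intrinsic_solubility": 0.0089,
  "solubility_factor": 50.0,
  "reference_solubility_pH2": 0.40,
  "fassif_solubility": 0.003,
  "fessif_solubility": 0.7,
  "solubilization_ratio": 80100.0,
  "effective_permeability": 0.00027,
  "fraction_unbound": 0.0457,
  "blood_plasma_ratio": 0.71,
  "hepatic_clearance": 4.0,
  "particle_radius": 15.0,
  "mean_precipitation_time": 100.0,
  "oral_bioavailability_F": 0.60
}
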