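{
  "_comment": "Editable quantification constants. Relaxation values are literature-style defaults per field strength and are fixture values, not measurements; override per study.",
  "water_concentration_mol_per_dm3": 55.51,
  "water_protons": 2,
  "tissue_water_density": {"GM": 0.78, "WM": 0.65, "CSF": 0.97},
  "t2_water_s": {
    "3T": {"GM": 0.11, "WM": 0.08, "CSF": 2.55},
    "7T": {"GM": 0.05, "WM": 0.055, "CSF": 1.05}
  },
  "t2_metabolite_s": {"3T": 0.271, "7T": 0.16},
  "default_reference_metabolite": "Cr",
  "default_reference_ppm_range": [2.0, 5.0]
}
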