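{
  "parameter_set_id": "vina_default",
  "comment": "Empirical pairwise scoring function of AutoDock Vina (Trott & Olson 2010). Terms are functions of the surface distance d = r - R_i - R_j (Angstrom). Weights in kcal/mol per unit term.",
  "weights": {
    "gauss1": -0.035579,
    "gauss2": -0.005156,
    "repulsion": 0.840245,
    "hydrophobic": -0.035069,
    "hbond": -0.587439
  },
  "shape": {
    "gauss1_offset": 0.0,
    "gauss1_width": 0.5,
    "gauss2_offset": 3.0,
    "gauss2_width": 2.0,
    "hydrophobic_good": 0.5,
    "hydrophobic_bad": 1.5,
    "hbond_good": -0.7,
    "hbond_bad": 0.0
  },
  "cutoff": 8.0,
  "rotor_weight": 0.05846
}
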