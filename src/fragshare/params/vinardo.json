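{
  "parameter_set_id": "vinardo_default",
  "comment": "Vinardo variant of the Vina empirical form (Quiroga & Villarreal 2016): single Gaussian, steeper repulsion weight, widened hydrophobic ramp and shortened H-bond ramp. gauss2 weight is zero.",
  "weights": {
    "gauss1": -0.045,
    "gauss2": 0.0,
    "repulsion": 0.8,
    "hydrophobic": -0.035,
    "hbond": -0.6
  },
  "shape": {
    "gauss1_offset": 0.0,
    "gauss1_width": 0.8,
    "gauss2_offset": 3.0,
    "gauss2_width": 2.0,
    "hydrophobic_good": 0.0,
    "hydrophobic_bad": 2.5,
    "hbond_good": -0.6,
    "hbond_bad": 0.0
  },
  "cutoff": 8.0,
  "rotor_weight": 0.05846
}
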