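{
  "table_id": "fragshare_types_v1",
  "comment": "Per-element interaction typing used by the built-in pairwise scoring backends. Radii are the heavy-atom vdW radii of the empirical backend family (Angstrom). Rules: carbon bonded only to C/H is hydrophobic; halogens are hydrophobic; N/O (and S) with an attached hydrogen are donors; N/O are acceptors.",
  "elements": {
    "C":  {"radius": 1.9, "hydrophobic_candidate": true,  "donor_candidate": false, "acceptor": false},
    "N":  {"radius": 1.8, "hydrophobic_candidate": false, "donor_candidate": true,  "acceptor": true},
    "O":  {"radius": 1.7, "hydrophobic_candidate": false, "donor_candidate": true,  "acceptor": true},
    "S":  {"radius": 2.0, "hydrophobic_candidate": false, "donor_candidate": true,  "acceptor": false},
    "P":  {"radius": 2.1, "hydrophobic_candidate": false, "donor_candidate": false, "acceptor": false},
    "F":  {"radius": 1.5, "hydrophobic_candidate": true,  "donor_candidate": false, "acceptor": false},
    "CL": {"radius": 1.8, "hydrophobic_candidate": true,  "donor_candidate": false, "acceptor": false},
    "BR": {"radius": 2.0, "hydrophobic_candidate": true,  "donor_candidate": false, "acceptor": false},
    "I":  {"radius": 2.2, "hydrophobic_candidate": true,  "donor_candidate": false, "acceptor": false},
    "SI": {"radius": 2.2, "hydrophobic_candidate": false, "donor_candidate": false, "acceptor": false},
    "B":  {"radius": 2.0, "hydrophobic_candidate": false, "donor_candidate": false, "acceptor": false},
    "FE": {"radius": 1.2, "hydrophobic_candidate": false, "donor_candidate": false, "acceptor": false},
    "ZN": {"radius": 1.2, "hydrophobic_candidate": false, "donor_candidate": false, "acceptor": false},
    "MG": {"radius": 1.2, "hydrophobic_candidate": false, "donor_candidate": false, "acceptor": false},
    "MN": {"radius": 1.2, "hydrophobic_candidate": false, "donor_candidate": false, "acceptor": false},
    "CA": {"radius": 1.2, "hydrophobic_candidate": false, "donor_candidate": false, "acceptor": false},
    "H":  {"radius": 0.0, "hydrophobic_candidate": false, "donor_candidate": false, "acceptor": false}
  }
}
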