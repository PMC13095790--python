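{
  "description": "Thoracic blood-pool partition for the circulating-blood dose model. Blood volume fractions follow the ICRP Publication 89 regional blood distribution, collapsed onto the contoured thoracic/upper-abdominal organs with the balance assigned to an out-of-field remainder compartment. Under renewal routing (next compartment drawn from the blood volume fractions) the long-run time occupancy equals blood_fraction * transit_s (normalized); per-visit transit times are therefore kept equal so that occupancy equals the blood volume fractions, the physically meaningful constraint, and they sum to 60 s per full circulation.",
  "source": "ICRP Publication 89 (2002), reference blood volume distribution",
  "compartments": [
    {"name": "aorta", "blood_fraction": 0.04, "transit_s": 6.666666666666667},
    {"name": "bronchi", "blood_fraction": 0.02, "transit_s": 6.666666666666667},
    {"name": "esophagus", "blood_fraction": 0.01, "transit_s": 6.666666666666667},
    {"name": "heart", "blood_fraction": 0.09, "transit_s": 6.666666666666667},
    {"name": "liver", "blood_fraction": 0.10, "transit_s": 6.666666666666667},
    {"name": "lungs", "blood_fraction": 0.105, "transit_s": 6.666666666666667},
    {"name": "pulmonary_artery", "blood_fraction": 0.03, "transit_s": 6.666666666666667},
    {"name": "vena_cava", "blood_fraction": 0.055, "transit_s": 6.666666666666667},
    {"name": "remainder", "blood_fraction": 0.55, "transit_s": 6.666666666666667}
  ]
}
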