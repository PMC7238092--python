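{
  "description": "Printed summary tables of the published two-reader breast-ultrasound CAD study this package reproduces: 512 surgically confirmed lesions (200 malignant, 312 benign), CAD read with the cross-planes and quadri-planes fusion rules, and a novice and an experienced reader each scored without CAD and combined with quadri-planes CAD. Counts transcribed from the study's contingency, agreement and decision-change tables.",
  "n_lesions": 512,
  "n_malignant": 200,
  "n_benign": 312,
  "contingency": {
    "cad_cross": {"tp": 190, "fp": 137, "fn": 10, "tn": 175},
    "cad_quadri": {"tp": 175, "fp": 58, "fn": 25, "tn": 254},
    "novice_without": {"tp": 120, "fp": 47, "fn": 80, "tn": 265},
    "novice_combined": {"tp": 158, "fp": 38, "fn": 42, "tn": 274},
    "experienced_without": {"tp": 152, "fp": 22, "fn": 48, "tn": 290},
    "experienced_combined": {"tp": 174, "fp": 40, "fn": 26, "tn": 272}
  },
  "agreement": {
    "experienced_without_vs_novice_without": {"pp": 121, "pn": 53, "np": 46, "nn": 292},
    "experienced_without_vs_novice_combined": {"pp": 141, "pn": 33, "np": 55, "nn": 283}
  },
  "decision_changes": {
    "novice": {
      "n_changed": 115,
      "upgrade_correct": 44,
      "upgrade_incorrect": 28,
      "downgrade_correct": 37,
      "downgrade_incorrect": 6
    },
    "experienced": {
      "n_changed": 70,
      "upgrade_correct": 27,
      "upgrade_incorrect": 28,
      "downgrade_correct": 10,
      "downgrade_incorrect": 5
    }
  }
}
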