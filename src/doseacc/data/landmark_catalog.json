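[
  {"index": 1, "name": "odontoid", "tissue": "bone"},
  {"index": 2, "name": "mandible_lower", "tissue": "bone"},
  {"index": 3, "name": "thyroid_notch", "tissue": "bone"},
  {"index": 4, "name": "hyoid_lesser_cornu_r", "tissue": "bone"},
  {"index": 5, "name": "hyoid_lesser_cornu_l", "tissue": "bone"},
  {"index": 6, "name": "sternum_superior_l", "tissue": "bone"},
  {"index": 7, "name": "c2_c3_disk_posterior", "tissue": "bone"},
  {"index": 8, "name": "vallecula", "tissue": "soft"},
  {"index": 9, "name": "philtrum", "tissue": "soft"},
  {"index": 10, "name": "palatine_uvula_lower", "tissue": "soft"},
  {"index": 11, "name": "carotid_bifurcation_r", "tissue": "soft"},
  {"index": 12, "name": "carotid_bifurcation_l", "tissue": "soft"},
  {"index": 13, "name": "parotid_r", "tissue": "soft"},
  {"index": 14, "name": "parotid_l", "tissue": "soft"}
]
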