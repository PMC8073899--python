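[
 {"name": "Sulfatide clearance agonist", "class": "clearance",
  "targets": [["SULF_CLEARANCE", 1], ["SULF_LYS", -1], ["SULF_REL", -1]]},
 {"name": "Glial calmative", "class": "anti-inflammatory",
  "targets": [["ASTRO_ACT", -1], ["MICRO_ACT", -1]]},
 {"name": "Remyelination promoter", "class": "myelin",
  "targets": [["DEMYELIN", -1]]},
 {"name": "Neuroprotectant", "class": "neuroprotective",
  "targets": [["NEURODEGEN", -1]]},
 {"name": "Neurotrophic supplement", "class": "supportive",
  "targets": [["NEURON", 1]]}
]
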