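[
 {"name": "Calcium channel blocker (VDCC)", "class": "calcium homeostasis", "targets": [["VDCC", -1]]},
 {"name": "Calpain inhibitor", "class": "calcium homeostasis", "targets": [["CALPAIN", -1]]},
 {"name": "Calpastatin agonist", "class": "calcium homeostasis", "targets": [["CALPASTATIN", 1]]},
 {"name": "Ipilimumab", "class": "checkpoint inhibitor", "targets": [["CTLA4", -1]]},
 {"name": "Pembrolizumab", "class": "checkpoint inhibitor", "targets": [["PD1", -1]]},
 {"name": "Cisplatin", "class": "chemotherapy", "targets": [["DNA_REPLICATION", -1]]},
 {"name": "Dichloroacetate", "class": "chemotherapy", "targets": [["PDK", -1]]},
 {"name": "Doxorubicin", "class": "chemotherapy", "targets": [["TOP2", -1]]},
 {"name": "Gemcitabine", "class": "chemotherapy", "targets": [["DNA_REPLICATION", -1]]},
 {"name": "Taxol", "class": "chemotherapy", "targets": [["MICROTUBULE", 1]]},
 {"name": "Afatinib", "class": "multitargeted", "targets": [["EGFR", -1], ["HER2", -1]]},
 {"name": "Alectinib", "class": "multitargeted", "targets": [["ALK", -1], ["RET", -1]]},
 {"name": "Brigatinib", "class": "multitargeted", "targets": [["ALK", -1], ["EGFR", -1]]},
 {"name": "Cabozantinib", "class": "multitargeted", "targets": [["VEGFR", -1], ["MET", -1], ["RET", -1]]},
 {"name": "Capmatinib", "class": "multitargeted", "targets": [["MET", -1]]},
 {"name": "Crizotinib", "class": "multitargeted", "targets": [["ALK", -1], ["MET", -1]]},
 {"name": "Imatinib", "class": "multitargeted", "targets": [["ABL", -1], ["KIT", -1], ["PDGFR", -1]]},
 {"name": "Lenvatinib", "class": "multitargeted", "targets": [["VEGFR", -1], ["FGFR", -1], ["RET", -1], ["KIT", -1]]},
 {"name": "Regorafenib", "class": "multitargeted", "targets": [["VEGFR", -1], ["RAF", -1], ["KIT", -1], ["RET", -1]]},
 {"name": "Sunitinib", "class": "multitargeted", "targets": [["VEGFR", -1], ["PDGFR", -1], ["KIT", -1]]},
 {"name": "Sorafenib", "class": "multitargeted", "targets": [["RAF", -1], ["VEGFR", -1], ["PDGFR", -1]]},
 {"name": "Dasatinib", "class": "multitargeted", "targets": [["SRC", -1], ["ABL", -1]]},
 {"name": "Nilotinib", "class": "multitargeted", "targets": [["ABL", -1], ["KIT", -1]]},
 {"name": "Erlotinib", "class": "multitargeted", "targets": [["EGFR", -1]]},
 {"name": "Pazopanib", "class": "multitargeted", "targets": [["VEGFR", -1], ["PDGFR", -1], ["KIT", -1]]},
 {"name": "Bortezomib", "class": "targeted", "targets": [["PROTEASOME", -1]]},
 {"name": "Nutlin3", "class": "targeted", "targets": [["MDM2", -1]]},
 {"name": "Olaparib", "class": "targeted", "targets": [["PARP", -1]]},
 {"name": "Rapamycin", "class": "targeted", "targets": [["MTOR", -1]]},
 {"name": "Tamoxifen", "class": "targeted", "targets": [["ER", -1]]},
 {"name": "Vitamin D3", "class": "targeted", "targets": [["VDR", 1]]},
 {"name": "Anakinra", "class": "targeted", "targets": [["IL1R", -1]]},
 {"name": "Jak2 inhibitor", "class": "targeted", "targets": [["JAK2", -1]]},
 {"name": "Rituximab", "class": "targeted", "targets": [["CD20", -1]]},
 {"name": "Tocilizumab", "class": "targeted", "targets": [["IL6R", -1]]},
 {"name": "Abemaciclib", "class": "targeted", "targets": [["CDK4", -1], ["CDK6", -1]]},
 {"name": "Bevacizumab", "class": "targeted", "targets": [["VEGFA", -1]]},
 {"name": "Cetuximab", "class": "targeted", "targets": [["EGFR", -1]]},
 {"name": "Palbociclib", "class": "targeted", "targets": [["CDK4", -1], ["CDK6", -1]]},
 {"name": "Enhertu", "class": "targeted", "targets": [["HER2", -1], ["TOP1", -1]]},
 {"name": "Ribociclib", "class": "targeted", "targets": [["CDK4", -1], ["CDK6", -1]]}
]
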