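{
 "name": "MLD disease profile",
 "entries": [
  ["ARSA", -1],
  ["ASTRO_ACT", 1],
  ["MICRO_ACT", 1],
  ["DEMENTIA", 1],
  ["DEMYELIN", 1],
  ["NEURODEGEN", 1],
  ["PERIPH_NEURO", 1],
  ["SEIZURES", 1],
  ["SULF_LYS", 1],
  ["SULF_REL", 1]
 ]
}
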