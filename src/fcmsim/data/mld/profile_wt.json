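{
 "name": "WT organoid profile",
 "entries": [
  ["RADIAL_GLIA", 1],
  ["NEURON", 1],
  ["OLIGO", 1]
 ]
}
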