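{
 "protocol": {
  "OCT4": {"value": 1.0, "locked": true},
  "SOX2": {"value": 1.0, "locked": true},
  "KLF4": {"value": 1.0, "locked": true},
  "CMYC": {"value": 1.0, "locked": true},
  "B27_MEDIA": {"value": 1.0, "locked": true}
 },
 "engine": {}
}
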