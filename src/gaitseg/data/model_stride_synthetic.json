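{
  "events": {
    "FF": 6,
    "HO": 26,
    "HS": 91,
    "TO": 39
  },
  "fs": 100.0
}
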