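{
  "DRB": 123,
  "DQ": 83,
  "DP": 62
}
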