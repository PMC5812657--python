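{
  "taxonomy": {
    "Aplastodiscus": 15,
    "Boana": 92,
    "Bokermannohyla": 32,
    "Hyloscirtus": 36,
    "Myersiohyla": 6
  },
  "c_bands_known": {
    "Aplastodiscus": 8,
    "Boana": 33,
    "Bokermannohyla": 9,
    "Hyloscirtus": 3
  }
}
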