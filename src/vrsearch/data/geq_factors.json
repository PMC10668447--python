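{
  "positive_affect": [1, 5, 9, 13, 17, 21, 25],
  "competence": [2, 6, 10, 14, 18],
  "negativity": [3, 7, 11, 15, 19, 22],
  "flow": [4, 8, 12, 16, 20, 23, 24]
}
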