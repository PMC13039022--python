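# loss-weight groups (alpha = VQ weight, beta = containment weight)
groups:
  - {name: group1, alpha: 0.2, beta: 0.8}
  - {name: group2, alpha: 0.4, beta: 0.6}   # default
  - {name: group3, alpha: 0.6, beta: 0.4}
  - {name: group4, alpha: 0.8, beta: 0.2}
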