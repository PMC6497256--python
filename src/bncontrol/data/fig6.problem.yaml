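externals:
- u
tau: 3
initial:
  v1: 0
  v2: 0
  v3: 0
  v4: 0
desired:
  v1: 1
  v2: 0
  v3: 0
  v4: 1
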