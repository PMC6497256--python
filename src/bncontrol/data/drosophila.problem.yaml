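externals:
- U1
- U2
- U3
tau: 6
initial:
  SLP: 0
  wg: 1
  WG: 1
  en: 0
  EN: 0
  hh: 1
  HH: 0
  ptc: 0
  PTC: 0
  PH: 0
  SMO: 0
  ci: 0
  CI: 1
  CIA: 0
  CIR: 1
desired:
  SLP: 0
  wg: 0
  WG: 0
  en: 1
  EN: 1
  hh: 0
  HH: 1
  ptc: 0
  PTC: 0
  PH: 0
  SMO: 1
  ci: 0
  CI: 0
  CIA: 0
  CIR: 0
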