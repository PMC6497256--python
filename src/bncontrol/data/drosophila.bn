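targets, factors
externals: U1, U2, U3
SLP, SLP
wg, (CIA & SLP & !CIR | wg & (CIA | SLP) & !CIR) & U2
WG, wg
en, !SLP
EN, en
hh, EN & !CIR & U3
HH, hh
ptc, CIA & !EN & !CIR & U1
PTC, ptc & PTC
PH, PTC
SMO, !PTC
ci, !EN
CI, ci
CIA, CI & SMO
CIR, CI & !SMO
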