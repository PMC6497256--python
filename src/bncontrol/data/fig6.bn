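targets, factors
externals: u
v1, u | !u & v2
v2, !u & v1
v3, v1
v4, v2 & v3
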