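m1	dA
m2	dB
m3	dC
m4	dD
m5	dE
m6	dF
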