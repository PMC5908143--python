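dA	C01
dB	C01.001
dC	C01.002
dD	C02.001
dE	C02.001.001
dF	C03
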