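	m1	m2	m3	m4	m5	m6	m7	m8
m1	1	0.8	0.8	0.1	0.1	0.1	0.1	0.1
m2	0.8	1	0.8	0.1	0.1	0.1	0.1	0.1
m3	0.8	0.8	1	0.1	0.1	0.1	0.1	0.1
m4	0.1	0.1	0.1	1	0.7	0.7	0.1	0.1
m5	0.1	0.1	0.1	0.7	1	0.7	0.1	0.1
m6	0.1	0.1	0.1	0.7	0.7	1	0.1	0.1
m7	0.1	0.1	0.1	0.1	0.1	0.1	1	0.6
m8	0.1	0.1	0.1	0.1	0.1	0.1	0.6	1
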