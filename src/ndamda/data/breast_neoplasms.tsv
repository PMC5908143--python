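rank	mirna	evidence
1	hsa-mir-16	dbdemc
2	hsa-mir-1247	Unconfirmed
3	hsa-mir-345	dbdemc
4	hsa-mir-143	dbdemc;miR2Disease
5	hsa-mir-215	dbdemc
6	hsa-mir-150	dbdemc
7	hsa-mir-15a	dbdemc
8	hsa-mir-15b	dbdemc
9	hsa-mir-10b	dbdemc;miR2Disease
10	hsa-mir-141	dbdemc;miR2Disease
11	hsa-mir-21	dbdemc;miR2Disease
12	hsa-mir-198	dbdemc
13	hsa-mir-590	dbdemc
14	hsa-mir-200a	dbdemc;miR2Disease
15	hsa-mir-29a	dbdemc
16	hsa-mir-26b	dbdemc
17	hsa-mir-675	Unconfirmed
18	hsa-mir-221	dbdemc;miR2Disease
19	hsa-mir-765	dbdemc
20	hsa-let-7a	dbdemc;miR2Disease
21	hsa-mir-29b	dbdemc;miR2Disease
22	hsa-mir-17	miR2Disease
23	hsa-mir-195	dbdemc;miR2Disease
24	hsa-mir-1	dbdemc
25	hsa-mir-103b	Unconfirmed
26	hsa-mir-181	Unconfirmed
27	hsa-mir-181c	dbdemc
28	hsa-mir-100	dbdemc
29	hsa-let-7c	dbdemc
30	hsa-mir-1302	Unconfirmed
31	hsa-mir-107	dbdemc
32	hsa-mir-503	dbdemc
33	hsa-mir-483	dbdemc
34	hsa-mir-33a	Unconfirmed
35	hsa-mir-422a	dbdemc
36	hsa-mir-200c	dbdemc;miR2Disease
37	hsa-mir-20a	miR2Disease
38	hsa-mir-133a	dbdemc
39	hsa-mir-498	dbdemc
40	hsa-mir-145	dbdemc;miR2Disease
41	hsa-mir-200b	dbdemc;miR2Disease
42	hsa-let-7d	dbdemc;miR2Disease
43	hsa-let-7b	dbdemc
44	hsa-mir-942	Unconfirmed
45	hsa-mir-518a	dbdemc
46	hsa-mir-181b	dbdemc;miR2Disease
47	hsa-mir-99b	dbdemc
48	hsa-mir-125a	dbdemc;miR2Disease
49	hsa-mir-27b	dbdemc
50	hsa-let-7g	dbdemc
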