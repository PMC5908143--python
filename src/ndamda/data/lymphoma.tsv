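rank	mirna	evidence
1	hsa-mir-1247	Unconfirmed
2	hsa-mir-215	dbdemc
3	hsa-mir-15b	dbdemc
4	hsa-mir-10b	dbdemc
5	hsa-mir-21	dbdemc;miR2Disease
6	hsa-mir-200a	dbdemc
7	hsa-let-7a	dbdemc
8	hsa-mir-26b	dbdemc
9	hsa-mir-221	dbdemc;miR2Disease
10	hsa-mir-17	dbdemc;miR2Disease
11	hsa-mir-33a	dbdemc
12	hsa-mir-195	dbdemc
13	hsa-mir-503	dbdemc
14	hsa-mir-130a	dbdemc
15	hsa-mir-103b	Unconfirmed
16	hsa-mir-1	dbdemc
17	hsa-mir-181c	dbdemc
18	hsa-mir-107	dbdemc
19	hsa-let-7c	dbdemc
20	hsa-mir-29b	dbdemc
21	hsa-mir-498	Unconfirmed
22	hsa-mir-200c	dbdemc
23	hsa-mir-1302	Unconfirmed
24	hsa-mir-942	Unconfirmed
25	hsa-mir-518a	Unconfirmed
26	hsa-mir-133a	dbdemc
27	hsa-mir-151	miR2Disease
28	hsa-mir-376c	Unconfirmed
29	hsa-mir-181d	dbdemc
30	hsa-mir-23a	dbdemc
31	hsa-mir-659	Unconfirmed
32	hsa-let-7d	dbdemc
33	hsa-mir-422a	dbdemc
34	hsa-mir-10a	dbdemc;miR2Disease
35	hsa-mir-483	Unconfirmed
36	hsa-mir-149	dbdemc;miR2Disease
37	hsa-mir-193b	Unconfirmed
38	hsa-mir-301b	Unconfirmed
39	hsa-mir-1323	Unconfirmed
40	hsa-let-7b	dbdemc
41	hsa-mir-20a	dbdemc;miR2Disease
42	hsa-mir-26a	dbdemc
43	hsa-let-7g	dbdemc
44	hsa-mir-31	dbdemc
45	hsa-mir-181b	dbdemc
46	hsa-mir-410	Unconfirmed
47	hsa-mir-125a	dbdemc
48	hsa-mir-200b	dbdemc
49	hsa-mir-204	dbdemc
50	hsa-mir-433	Unconfirmed
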