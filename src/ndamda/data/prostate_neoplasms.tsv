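rank	mirna	evidence
1	hsa-mir-21	dbdemc;miR2Disease
2	hsa-mir-155	dbdemc
3	hsa-mir-146a	miR2Disease
4	hsa-mir-125b	dbdemc;miR2Disease;HMDD
5	hsa-mir-17	miR2Disease
6	hsa-mir-20a	miR2Disease
7	hsa-mir-34a	dbdemc;miR2Disease
8	hsa-mir-145	dbdemc;miR2Disease;HMDD
9	hsa-mir-221	dbdemc;miR2Disease
10	hsa-mir-18a	Unconfirmed
11	hsa-mir-16	dbdemc;miR2Disease
12	hsa-mir-92a	Unconfirmed
13	hsa-mir-126	dbdemc;miR2Disease
14	hsa-mir-19b	dbdemc;miR2Disease
15	hsa-mir-15a	dbdemc;miR2Disease
16	hsa-mir-19a	dbdemc
17	hsa-mir-29a	dbdemc;miR2Disease
18	hsa-mir-1	dbdemc
19	hsa-mir-222	dbdemc;miR2Disease
20	hsa-mir-143	dbdemc;miR2Disease
21	hsa-mir-29b	dbdemc;miR2Disease
22	hsa-let-7a	dbdemc;miR2Disease
23	hsa-mir-200b	Unconfirmed
24	hsa-mir-223	dbdemc;miR2Disease
25	hsa-mir-29c	dbdemc
26	hsa-mir-31	dbdemc;miR2Disease
27	hsa-mir-199a	dbdemc;miR2Disease
28	hsa-mir-9	dbdemc
29	hsa-mir-181a	dbdemc;miR2Disease
30	hsa-mir-133a	dbdemc
31	hsa-mir-210	miR2Disease
32	hsa-let-7b	dbdemc;miR2Disease
33	hsa-mir-200a	dbdemc
34	hsa-mir-200c	dbdemc
35	hsa-mir-181b	dbdemc;miR2Disease
36	hsa-mir-142	Unconfirmed
37	hsa-mir-150	dbdemc
38	hsa-mir-34c	dbdemc
39	hsa-let-7c	dbdemc;miR2Disease
40	hsa-mir-146b	Unconfirmed
41	hsa-mir-122	Unconfirmed
42	hsa-mir-106b	dbdemc
43	hsa-mir-182	dbdemc;miR2Disease
44	hsa-let-7d	dbdemc;miR2Disease
45	hsa-mir-141	miR2Disease
46	hsa-let-7e	dbdemc
47	hsa-mir-133b	dbdemc
48	hsa-mir-214	dbdemc;miR2Disease
49	hsa-mir-203	Unconfirmed
50	hsa-mir-30a	miR2Disease
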