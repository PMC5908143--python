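rank	mirna	evidence
1	hsa-mir-146a	dbdemc
2	hsa-mir-133b	dbdemc
3	hsa-mir-1247	Unconfirmed
4	hsa-mir-205	dbdemc;miR2Disease
5	hsa-mir-152	dbdemc
6	hsa-mir-345	dbdemc
7	hsa-mir-143	dbdemc
8	hsa-mir-215	dbdemc
9	hsa-mir-148b	dbdemc
10	hsa-mir-449b	Unconfirmed
11	hsa-mir-15a	dbdemc
12	hsa-mir-150	dbdemc
13	hsa-mir-140	dbdemc
14	hsa-mir-10b	dbdemc
15	hsa-mir-1972	Unconfirmed
16	hsa-mir-15b	dbdemc
17	hsa-mir-21	dbdemc;miR2Disease
18	hsa-mir-198	dbdemc
19	hsa-mir-141	dbdemc
20	hsa-mir-590	dbdemc
21	hsa-mir-200a	dbdemc
22	hsa-mir-29a	dbdemc
23	hsa-mir-26b	dbdemc
24	hsa-mir-675	Unconfirmed
25	hsa-mir-221	dbdemc
26	hsa-mir-765	dbdemc
27	hsa-mir-29b	dbdemc
28	hsa-mir-195	dbdemc
29	hsa-let-7a	dbdemc
30	hsa-mir-17	dbdemc
31	hsa-mir-1	dbdemc
32	hsa-mir-181	Unconfirmed
33	hsa-mir-103b	Unconfirmed
34	hsa-mir-181c	dbdemc
35	hsa-mir-100	dbdemc
36	hsa-mir-1302	Unconfirmed
37	hsa-mir-483	dbdemc
38	hsa-let-7c	dbdemc
39	hsa-mir-20a	dbdemc
40	hsa-mir-422a	dbdemc
41	hsa-mir-145	dbdemc
42	hsa-mir-200b	dbdemc
43	hsa-mir-107	dbdemc;miR2Disease
44	hsa-let-7b	dbdemc
45	hsa-mir-133a	dbdemc
46	hsa-mir-200c	dbdemc
47	hsa-let-7d	dbdemc
48	hsa-mir-498	dbdemc
49	hsa-mir-503	dbdemc
50	hsa-mir-181b	dbdemc
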