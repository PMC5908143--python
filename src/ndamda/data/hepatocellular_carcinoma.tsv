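rank	mirna	evidence
1	hsa-mir-155	miR2Disease;HMDD
2	hsa-mir-16	miR2Disease;HMDD
3	hsa-mir-208	Unconfirmed
4	hsa-let-7a	miR2Disease;HMDD
5	hsa-mir-15a	miR2Disease;HMDD
6	hsa-mir-598	Unconfirmed
7	hsa-mir-539	Unconfirmed
8	hsa-mir-550	Unconfirmed
9	hsa-mir-652	Unconfirmed
10	hsa-let-7b	miR2Disease;HMDD
11	hsa-mir-328	miR2Disease
12	hsa-let-7c	miR2Disease;HMDD
13	hsa-let-7i	HMDD
14	hsa-let-7d	miR2Disease;HMDD
15	hsa-mir-411	Unconfirmed
16	hsa-mir-29b	HMDD
17	hsa-mir-143	miR2Disease
18	hsa-mir-181b	miR2Disease;HMDD
19	hsa-mir-126	miR2Disease;HMDD
20	hsa-let-7g	miR2Disease;HMDD
21	hsa-let-7f	miR2Disease;HMDD
22	hsa-mir-146b	HMDD
23	hsa-mir-106b	miR2Disease;HMDD
24	hsa-mir-29a	HMDD
25	hsa-mir-214	miR2Disease;HMDD
26	hsa-mir-133a	miR2Disease
27	hsa-mir-150	miR2Disease;HMDD
28	hsa-mir-24	miR2Disease;HMDD
29	hsa-mir-132	miR2Disease
30	hsa-mir-141	miR2Disease;HMDD
31	hsa-mir-9	miR2Disease
32	hsa-mir-29c	HMDD
33	hsa-mir-15b	HMDD
34	hsa-mir-181a	miR2Disease;HMDD
35	hsa-mir-210	HMDD
36	hsa-mir-30c	miR2Disease;HMDD
37	hsa-mir-107	miR2Disease;HMDD
38	hsa-mir-194	miR2Disease
39	hsa-mir-30d	HMDD
40	hsa-mir-373	HMDD
41	hsa-mir-205	miR2Disease;HMDD
42	hsa-mir-30a	miR2Disease;HMDD
43	hsa-mir-200c	HMDD
44	hsa-mir-25	miR2Disease;HMDD
45	hsa-mir-196a	HMDD
46	hsa-mir-191	HMDD
47	hsa-mir-32	Unconfirmed
48	hsa-mir-93	miR2Disease;HMDD
49	hsa-mir-451	Unconfirmed
50	hsa-mir-34c	HMDD
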