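row_no	mirna	cluster	T2	T2_sig	T3	T3_sig	T4	T4_sig	T5	T5_sig	T6	T6_sig
1	ssa-let-7b-3p	I	-1.02	True	-0.39	False	-0.52	False	-1.29	True	-0.80	False
2	ssa-miR-20b-5p	I	-0.61	False	-0.82	False	-0.92	False	-0.98	False	-1.23	True
3	ssa-miR-30a-3-4-3p	I	-0.37	False	-0.54	False	-0.93	False	-0.66	False	-1.05	True
4	ssa-miR-125b-1-3p	I	-0.74	False	-1.18	True	-1.51	True	-1.38	True	-1.62	True
5	ssa-miR-130d-2-5p	I	-0.63	False	-1.30	False	-1.30	False	-1.38	True	-1.26	True
6	ssa-miR-135a-3p	I	-0.70	False	-0.46	False	-0.75	False	-0.77	False	-1.63	True
7	ssa-miR-192a-5p	I	-0.87	False	-1.67	False	-4.44	True	-3.16	True	-5.24	True
8	ssa-miR-194a-5p	I	-2.06	False	-3.01	True	-4.02	True	-3.22	True	-5.17	True
9	ssa-miR-196a-5p	I	-0.36	False	-0.13	False	-0.89	False	-0.49	False	-1.00	True
10	ssa-miR-200ae-3p	I	-0.69	False	-3.12	True	-4.40	True	-2.90	True	-5.60	True
11	ssa-miR-200b-3p	I	-1.54	False	-2.85	True	-3.91	True	-3.89	True	-5.07	True
12	ssa-miR-203a-3p	I	0.96	False	-0.85	False	-1.25	True	-0.39	False	-1.16	True
13	ssa-miR-205b-5p	I	1.29	False	-0.99	False	-1.80	True	-1.46	True	-3.05	True
14	ssa-miR-222b-5p	I	-0.90	False	-0.63	False	-0.75	False	-1.24	True	-1.00	False
15	ssa-miR-301a-5p	I	-1.07	False	-1.59	False	-2.00	True	-2.37	True	-1.69	True
16	ssa-miR-375-3p	I	-0.58	False	-0.40	False	-1.02	True	-0.07	False	-0.90	False
17	ssa-miR-429ab-3p	I	-0.60	False	-1.63	False	-4.08	True	-2.48	True	-5.23	True
18	ssa-miR-430b-5p	I	-0.84	False	-0.61	False	-1.51	True	-1.88	True	-1.71	True
19	ssa-miR-449ab-5p	I	-0.82	False	-1.44	False	-2.57	True	-1.98	False	-4.44	True
20	ssa-miR-722-3p	I	-0.26	False	-0.79	False	-1.61	True	-0.65	False	-1.36	True
21	ssa-miR-8162-5p	I	-0.79	False	-0.97	False	-1.20	True	-0.99	False	-0.79	False
22	ssa-miR-novel-2-5p	I	-1.11	False	-1.48	True	-2.35	True	-1.51	True	-2.42	True
23	ssa-miR-novel-15-3p	I	-0.78	False	-1.32	True	-1.55	True	-0.96	False	-1.02	True
24	ssa-miR-1-3p	II	-0.05	False	-1.24	False	0.15	False	-1.31	True	-0.99	False
25	ssa-miR-15b-3p	II	-0.48	False	-0.22	False	-0.61	False	-1.30	True	-0.22	False
26	ssa-miR-30a-2-3p	II	-1.11	True	-0.73	False	-0.94	False	-0.97	False	-0.85	False
27	ssa-miR-92a-1-2-5p	II	-1.01	True	-0.21	False	-0.58	False	-0.42	False	-0.18	False
28	ssa-miR-106b-3p	II	-0.86	False	-0.46	False	-0.97	False	-1.56	True	-0.45	False
29	ssa-miR-125a-1-3p	II	-1.61	True	-0.37	False	-0.02	False	-0.26	False	-0.41	False
30	ssa-miR-133-4-5p	II	-0.95	False	-1.26	False	-0.72	False	-1.76	False	-1.19	True
31	ssa-miR-144-3p	II	-0.40	False	-0.10	False	0.03	False	-1.53	True	0.69	False
32	ssa-miR-144-5p	II	-0.80	False	-0.38	False	-0.33	False	-2.35	True	0.42	False
33	ssa-miR-301b-5p	II	-1.17	True	-0.65	False	-0.26	False	-1.02	True	-0.38	False
34	ssa-miR-451-3p	II	-0.96	False	-1.01	True	-0.86	False	-1.68	True	0.27	False
35	ssa-miR-730a-5p	II	-0.37	False	-0.11	False	0.10	False	-2.89	True	0.50	False
36	ssa-miR-2188-3p	II	-0.30	False	0.37	False	0.68	False	-1.33	True	0.99	False
37	ssa-miR-novel-12-5p	II	-0.77	False	-0.38	False	-0.69	False	-1.05	True	-0.29	False
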