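row_no	mirna	cluster	T2	T2_sig	T3	T3_sig	T4	T4_sig	T5	T5_sig	T6	T6_sig
1	ssa-miR-17-1-3p	III	0.36	False	0.69	False	0.92	False	0.78	False	1.06	True
2	ssa-miR-29b-1-5p	III	0.84	False	1.21	True	1.59	True	1.44	True	0.76	False
3	ssa-miR-100a-2-3p	III	0.22	False	0.77	False	0.98	False	1.11	True	1.10	True
4	ssa-miR-132-1-2-5p	III	0.50	False	0.39	False	0.57	False	1.21	True	0.77	False
5	ssa-miR-137a-3p	III	0.34	False	0.23	False	0.80	False	1.01	True	0.84	False
6	ssa-miR-146a-5p	III	0.58	False	0.62	False	0.77	False	1.28	True	1.00	True
7	ssa-miR-150-3p	III	0.48	False	0.56	False	1.10	True	0.25	False	0.17	False
8	ssa-miR-153a-3p	III	0.51	False	0.52	False	0.46	False	1.08	True	0.95	False
9	ssa-miR-202b-5p	III	1.13	False	0.76	False	1.18	False	1.56	False	2.08	True
10	ssa-miR-204-5p	III	0.35	False	0.51	False	0.72	False	1.27	True	1.01	True
11	ssa-miR-216a-5p	III	1.42	True	0.44	False	0.84	False	0.13	False	0.74	False
12	ssa-miR-217-5p	III	1.15	True	-0.35	False	0.44	False	-0.17	False	0.40	False
13	ssa-miR-218a-5p	III	0.32	False	0.51	False	0.79	False	1.23	True	1.02	True
14	ssa-miR-451-5p	III	0.44	False	0.51	False	0.71	False	0.27	False	1.01	True
15	ssa-miR-725-3p	III	1.46	True	-0.19	False	-0.39	False	0.44	False	0.17	False
16	ssa-miR-727a-5p	III	0.70	False	1.12	True	0.91	False	0.30	False	-0.01	False
17	ssa-miR-8158-3p	III	0.58	False	0.52	False	1.02	True	1.27	True	1.25	True
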