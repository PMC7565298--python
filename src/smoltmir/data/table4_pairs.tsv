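row_no	gene	mirna	cluster	major_expressed
1	cxa1	ssa-miR-30e-3-3p	I	False
1	cxa1	ssa-let-7b-3p	I	True
1	cxa1	ssa-miR-194a-3p	I	False
2	apoa1bp	ssa-miR-novel-15-3p	I	True
3	star_paralog_1	ssa-miR-30e-3-3p	I	False
4	star_paralog_2	ssa-miR-205b-5p	I	True
5	fdx1l	ssa-miR-722-3p	I	True
6	spink1	ssa-miR-196a-5p	I	True
6	spink1	ssa-miR-196b-5p	I	False
7	ptdss1	ssa-miR-17-1-3p	III	True
8	agtrap	ssa-miR-17-1-3p	III	True
9	gulp1	ssa-miR-17-1-3p	III	True
10	spint2	ssa-miR-17-1-3p	III	True
10	spint2	ssa-miR-217-5p	III	True
11	grb14	ssa-miR-17-1-3p	III	True
11	grb14	ssa-miR-204-5p	III	True
11	grb14	ssa-miR-218a-5p	III	True
12	trhde.2	ssa-miR-137a-3p	III	True
12	trhde.2	ssa-miR-29c-5p	III	False
13	lpl	ssa-miR-137a-3p	III	True
14	epn	ssa-miR-137a-3p	III	True
14	epn	ssa-miR-29b-3p	III	False
14	epn	ssa-miR-29a-3p	III	False
15	pnmt	ssa-miR-146a-5p	III	True
15	pnmt	ssa-miR-146b-5p	III	False
16	nrip2	ssa-miR-146a-5p	III	True
16	nrip2	ssa-miR-217-5p	III	True
16	nrip2	ssa-miR-725-3p	III	True
16	nrip2	ssa-miR-202a-5p	III	False
16	nrip2	ssa-miR-204-5p	III	True
16	nrip2	ssa-miR-146b-5p	III	False
17	nid1	ssa-miR-146b-5p	III	False
18	s47a1	ssa-miR-146b-5p	III	False
19	acy2	ssa-miR-204-5p	III	True
20	sepp1	ssa-miR-204-5p	III	True
21	itga6	ssa-miR-204-5p	III	True
22	slc16a7	ssa-miR-204-5p	III	True
22	slc16a7	ssa-miR-217-5p	III	True
22	slc16a7	ssa-miR-8158-3p	III	True
23	acy3	ssa-miR-204-5p	III	True
24	rmdn2	ssa-miR-216a-5p	III	True
25	cdo1	ssa-miR-216a-5p	III	True
26	slc15a2	ssa-miR-217-5p	III	True
27	loc106561979	ssa-miR-217-5p	III	True
27	loc106561979	ssa-miR-727a-5p	III	True
28	aqp8	ssa-miR-217-5p	III	True
29	igfbp5	ssa-miR-217-5p	III	True
30	gucy2f	ssa-miR-217-5p	III	True
30	gucy2f	ssa-miR-725-3p	III	True
31	gat2	ssa-miR-218a-5p	III	True
32	slco1a2	ssa-miR-218a-5p	III	True
32	slco1a2	ssa-miR-146a-3-3p	III	False
33	gfra1	ssa-miR-218a-5p	III	True
33	gfra1	ssa-miR-727a-5p	III	True
34	loc106610933	ssa-miR-150-3p	III	True
35	npt2a	ssa-miR-29c-5p	III	False
36	prss23	ssa-miR-29b-3p	III	False
36	prss23	ssa-miR-29a-3p	III	False
37	cld3	ssa-miR-29b-3p	III	False
37	cld3	ssa-miR-29a-3p	III	False
38	pfkfb1	ssa-miR-725-3p	III	True
39	sell	ssa-miR-725-3p	III	True
40	cisd1	ssa-miR-725-3p	III	True
41	wt1	ssa-miR-727a-5p	III	True
41	wt1	ssa-miR-29c-5p	III	False
42	capsl	ssa-miR-132-1-2-5p	III	True
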