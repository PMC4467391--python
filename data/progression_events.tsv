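chrom	start_mb	end_mb	length_mb	cytobands	type	n_genes	DCIS 1	DCIS 2 complete	DCIS 2 subclone	Primary tumor complete	Primary tumor subclone	Metastasis complete	Metastasis subclone
2	0	243.19	243.19	p25.3–q37.3	LOH	1545	x	x	x	x	x	x	x
4	0	49.53	49.53	p16.3–p11	LOH	346	x	x	x	x	x	x	x
6	68.64	160.13	91.48	q12–q25.3	LOH	439	x	x	x	x	x	x	x
8	0	37.68	37.68	p23.3–p11.23	LOH	306	x	x	x	x	x	x	x
8	7.04	8.06	1.02	p23.1	HL	46	x	x	x	x	x	x	x
8	11.88	12.42	0.54	p23.1	HL	18	x	x	x	x	x	x	x
8	39.44	41.05	1.61	p11.22–11.21	LOH	6	x	x	x	x	x	x	x
9	68.18	130.82	62.64	q13–q34.11	LOH	470	x	x	x	x	x	x	x
11	62.41	68.28	5.86	q12.3–q13.2	LOH	240	x	x	x	x	x	x	x
11	71.11	75.90	4.79	q13.4–q13.5	LOH	79	x	x	x	x	x	x	x
11	85.72	87.59	1.87	q14.2	LOH	11	x	x	x	x	x	x	x
11	100.81	135.00	34.19	q22.1–q25	LOH	322	x	x	x	x	x	x	x
13	16.48	115.16	98.68	p11.1–q34	LOH	518	x	x	x	x	x	x	x
14	43.95	80.13	36.17	q21.2–q31.1	LOH	287	x	x	x	x	x	x	x
14	84.27	106.74	22.47	q31.2–q32.33	LOH	285	x	x	x	x	x	x	x
16	0.08	1.4	1.31	p13.3	LOH	65	x	x	x	x	x	x	x
16	3.04	4.48	1.44	p13.3	LOH	46	x	x	x	x	x	x	x
16	24.56	27.43	2.87	p12.1	LOH	16	x	x	x	x	x	x	x
16	32.60	33.37	0.77	p11.2	LOH	11	x	x	x	x	x	x	x
16	33.55	34.46	0.90	p11.2	LOH	3	x	x	x	x	x	x	x
16	45.61	90.35	44.74	q11.2–q24.3	LOH	446	x	x	x	x	x	x	x
17	0	22.59	22.59	p13.3–p11.1	LOH	414	x	x	x	x	x	x	x
17	25.29	41.45	16.16	q11.1–q21.31	LOH	400	x	x	x	x	x	x	x
19	57.79	59.12	1.33	q13.43	LOH	66	x	x	x	x	x	x	x
21	45.68	48.12	2.44	q22.3	LOH	63	x	x	x	x	x	x	x
8	112.88	146.36	33.47	q23.3–q24.3	OCL	235			x	x	x	x	x
9	0	44.41	44.41	p24.3–p11.2	LOH	283			x	x	x	x	x
20	0	11.90	11.90	p13–p12.2	LOH	136			x	x	x	x	x
1	26.08	107.60	81.51	p36.11–p13.3	LOH	717				x	x	x	x
20	31.89	32.83	0.93	q11.21–11.22	LOH	15				x	x	x	x
22	16.39	42.11	25.72	q11.1–q13.2	LOH	433				x	x	x	x
22	42.45	42.77	0.31	q13.2	LOH	9				x	x	x	x
19	0.03	20.88	20.85	p13.3–p12	LOH	648					x	x	x
20	11.93	21.5	9.56	p12.2–p11.22	LOH	55					x	x	x
10	65.05	135.53	70.47	q21.3–q26.3	LOH	608						x	x
3	0	76.53	76.53	p26.3–p12.3	LOH	592							x
4	50.40	191.15	140.75	q11–q35.2	LOH	664							x
5	0	77.46	77.46	p15.33–q14.1	LOH	395							x
7	0	159.13	159.13	p22.3–q36.3	HL	1190							x
8	52.54	53.33	0.78	q11.22–11.23	LOH	3							x
8	55.37	67.35	11.98	q11.23–q13.1	LOH	59							x
8	68.34	86.56	18.22	q13.2–q21.2	LOH	76							x
9	130.73	141.21	10.48	q34.11–q34.3	LOH	252							x
10	0	65.05	65.05	p15.3–q21.3	LOH	387							x
14	18.80	42.09	23.28	q11.2–q21.1	LOH	227							x
15	19.96	42.13	22.16	q11.1–q15.1	HL	323							x
15	42.16	102.53	60.36	q15.1–q26.3	LOH	590							x
21	9.74	45.93	36.19	p11.2–q22.3	LOH	270							x
X	0	42.79	42.79	p22.33–p11.3	LOH	209							x
X	55.11	60.60	5.48	p11.21–q11.1	LOH	20							x
X	61.69	102.34	40.65	q11.1–q22.1	LOH	198							x
X	106.50	132.09	25.58	q22.3–q26.2	LOH	230							x
8	87.65	146.36	58.71	q21.3–q24.3	HCG	359	x	x	x	x	x	x	x
11	68.28	71.11	2.82	q13.2–q13.4	EHCG	26	x	x	x	x	x	x	x
11	75.90	85.33	9.43	q13.5–q14.1	VHCG	44	x	x	x	x	x	x	x
11	88.30	89.46	1.16	q14.3	CG	5	x	x	x	x	x	x	x
11	89.53	94.56	5.02	q14.3–q21	VHCG	46	x	x	x	x	x	x	x
16	1.40	2.79	1.39	p13.3	CG	80	x	x	x	x	x	x	x
16	15.50	18.43	2.93	p13.11–p12.3	CG	29	x	x	x	x	x	x	x
16	18.81	20.38	1.57	p12.3	CG	18	x	x	x	x	x	x	x
16	20.80	24.56	3.76	p12.3–p12.1	VHCG	50	x	x	x	x	x	x	x
16	27.67	31.99	4.32	p12.1–p11.2	VHCG	154	x	x	x	x	x	x	x
18	55.39	63.42	8.03	q21.31–q22.1	VHCG	42	x	x	x	x	x	x	x
17	41.44	43.34	1.89	q21.31	CG	58		x	x	x	x	x	x
17	44.23	81.19	36.96	q21.31–q25.3	CG	542		x	x	x	x	x	x
19	53.65	56.85	3.20	q13.42–q13.43	CG	181		x	x	x	x	x	x
X	142.23	144.43	2.10	q27.3–q28	CG	5		x	x	x	x	x	x
X	146.55	151.56	5.00	q27.3–q28	CG	45		x	x	x	x	x	x
1	187.21	192.62	5.41	q31.1–q31.2	HCG	6				x	x	x	x
1	192.62	197.10	4.47	q31.2–q31.3	CG	18				x	x	x	x
1	197.10	215.74	18.64	q31.3–q41	HCG	202				x	x	x	x
1	215.74	218.50	2.75	q41	CG	7				x	x	x	x
20	21.37	26.06	4.98	p11.22–p11.1	CG	47				x	x	x	x
20	33.71	52.66	18.95	q11.22–q13.2	CG	222				x	x	x	x
22	46.66	50.65	3.98	q13.31–q13.33	HCG	29				x	x	x	x
X	144.43	146.55	2.12	q27.3	CG	30				x	x	x	x
X	151.56	155.05	3.49	q28	CG	133				x	x	x	x
1	218.50	219.37	0.86	q41	HCG	5						x	x
6	150.76	152.61	1.84	q25.1–q25.2	VHCG	9						x	x
8	49.26	51.67	2.40	q11.21	VHCG	6						x	x
8	51.67	52.54	0.86	q11.21–q11.22	CG	2						x	x
8	53.34	55.37	2.03	q11.23	VHCG	10						x	x
8	67.35	68.34	0.98	q13.1–q13.2	VHCG	17						x	x
8	100.58	111.46	10.87	q22.2–q23.2	EHCG	53						x	x
12	57.92	58.32	0.39	q13.3–q14.1	CG	22						x	x
17	46.04	46.57	0.52	q21.32	VHCG	8						x	x
17	47.36	81.08	33.71	q21.32–q25.3	VHCG	469						x	x
19	53.65	56.85	3.20	q13.42–q13.43	VHCG	181						x	x
20	29.89	31.89	1.99	q11.21	CG	47						x	x
22	46.66	50.65	3.98	q13.31–q13.33	VHCG	29						x	x
X	43.26	45.24	1.97	p11.3	CG	8						x	x
X	45.59	51.07	5.48	p11.3–p11.22	CG	157						x	x
X	51.64	54.31	2.67	p11.22	CG	67						x	x
X	142.32	144.43	2.11	q27.3	HCG	5						x	x
X	146.55	151.56	5.00	q27.3–q28	VHCG	45						x	x
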