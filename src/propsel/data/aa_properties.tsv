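# Default amino-acid physicochemical property table: 20 properties x 20 amino acids.
# Values compiled from the standard experimental scales cited in the molecular-adaptation
# literature (AAindex-style). This table is configuration: substitute your own TSV with
# the same layout to use different value sets.
property	description	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
pK'	Equilibrium constant (ionization of COOH)	2.34	1.71	1.88	2.19	1.83	2.34	1.82	2.36	2.18	2.36	2.28	2.02	1.99	2.17	2.17	2.21	2.63	2.32	2.38	2.20
Ra	Solvent accessible reduction ratio	0.74	0.91	0.62	0.58	0.88	0.72	0.78	0.88	0.52	0.85	0.85	0.63	0.64	0.62	0.64	0.66	0.70	0.86	0.85	0.76
an	Power to be at the N-terminal	1.29	0.79	1.47	1.44	1.07	1.07	1.09	0.97	1.23	1.31	1.30	0.90	0.52	1.27	0.96	0.82	0.82	0.91	0.99	0.72
Hp	Surrounding hydrophobicity	12.97	14.63	10.85	11.89	14.00	12.43	12.16	15.67	11.36	14.90	14.39	11.42	11.37	11.76	11.72	11.23	11.69	15.71	13.93	13.42
H	Hydropathy	1.8	2.5	-3.5	-3.5	2.8	-0.4	-3.2	4.5	-3.9	3.8	1.9	-3.5	-1.6	-3.5	-4.5	-0.8	-0.7	4.2	-0.9	-1.3
Ko	Compressibility	-25.5	-32.8	-33.1	-36.2	-32.6	-27.0	-31.0	-31.8	-35.5	-31.7	-31.5	-30.9	-23.3	-32.6	-26.7	-29.3	-31.0	-30.4	-30.5	-34.9
F	Mean r.m.s. fluctuation displacement	0.68	0.40	0.82	0.92	0.52	0.90	0.59	0.47	1.02	0.49	0.53	0.82	0.77	0.84	0.73	0.85	0.74	0.46	0.45	0.59
Ht	Thermodynamic transfer hydrophobicity	0.87	1.52	0.66	0.67	2.87	0.10	0.87	3.15	1.64	2.17	1.67	0.09	2.77	0.00	0.85	0.07	0.07	1.87	3.77	2.67
P	Polarity	8.1	5.5	13.0	12.3	5.2	9.0	10.4	5.2	11.3	4.9	5.7	11.6	8.0	10.5	10.5	9.2	8.6	5.9	5.4	6.2
Pa	Alpha-helical tendency	1.42	0.70	1.01	1.51	1.13	0.57	1.00	1.08	1.16	1.21	1.45	0.67	0.57	1.11	0.98	0.77	0.83	1.06	1.08	0.69
Pb	Beta-structure tendency	0.83	1.19	0.54	0.37	1.38	0.75	0.87	1.60	0.74	1.30	1.05	0.89	0.55	1.10	0.93	0.75	1.19	1.70	1.37	1.47
Pc	Coil tendency	0.66	1.19	1.46	0.74	0.60	1.56	0.95	0.47	1.01	0.59	0.60	1.56	1.52	0.98	0.95	1.43	0.96	0.50	0.96	1.14
Bl	Bulkiness	11.50	13.46	11.68	13.57	19.80	3.40	13.69	21.40	15.71	21.40	16.25	12.82	17.43	14.45	14.28	9.47	15.77	21.57	21.67	18.03
pHi	Isoelectric point	6.00	5.05	2.77	3.22	5.48	5.97	7.59	6.02	9.74	5.98	5.74	5.41	6.30	5.65	10.76	5.68	5.66	5.96	5.89	5.66
Mv	Molecular volume	31.0	55.0	54.0	83.0	132.0	3.0	96.0	111.0	119.0	111.0	105.0	56.0	32.5	85.0	124.0	32.0	61.0	84.0	170.0	136.0
mu	Refractive index	4.34	35.77	12.00	17.26	29.40	0.00	21.81	19.06	21.29	18.78	21.64	13.28	10.93	17.56	26.66	6.35	11.01	13.92	42.53	31.53
Pr	Polar requirement	7.0	4.8	13.0	12.5	5.0	7.9	8.4	4.9	10.1	4.9	5.3	10.0	6.6	8.6	9.1	7.5	6.6	5.6	5.2	5.4
Bu	Buriedness	0.38	0.45	0.15	0.18	0.50	0.36	0.17	0.60	0.03	0.45	0.40	0.12	0.18	0.07	0.01	0.22	0.23	0.54	0.27	0.15
Vo	Partial specific volume	0.748	0.631	0.579	0.643	0.774	0.632	0.670	0.884	0.789	0.884	0.745	0.619	0.758	0.674	0.666	0.613	0.689	0.847	0.734	0.712
Esm	Short and medium range non-bonded energy	-1.26	-1.55	-1.29	-1.31	-2.03	-1.34	-1.70	-1.88	-1.36	-1.85	-1.82	-1.21	-1.32	-1.25	-1.55	-1.15	-1.39	-1.75	-2.34	-2.01
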