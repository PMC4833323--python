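species	group	ref_f	ref_m	nt_all_coding	nt_pcgs	nt_rrnas	nt_trnas	nt_atp6	nt_atp8	nt_cox1	nt_cox2	nt_cox3	nt_cytb	nt_nad1	nt_nad2	nt_nad3	nt_nad4	nt_nad4L	nt_nad5	nt_nad6	nt_rrnL	nt_rrnS	aa_pcgs	aa_atp6	aa_atp8	aa_cox1	aa_cox2	aa_cox3	aa_cytb	aa_nad1	aa_nad2	aa_nad3	aa_nad4	aa_nad4L	aa_nad5	aa_nad6
Anodonta anatina	Unionoidea	NC_022803	KF030963	92.24	90.02	98.76	112.28	114.22	109.70	80.86	88.62	78.97	85.97	90.20	100.78	90.00	96.48	48.03	88.90	119.64	98.99	98.70	81.46	87.98	186.71	42.34	82.92	54.98	54.35	66.80	133.98	98.29	150.76	92.06	101.01	194.11
Hyriopsis cumingii	Hyriopsis	NC_011763	HM347668	10.09	11.59	5.80	4.85	10.70	4.32	7.04	14.78	9.96	12.80	13.82	16.56	5.59	10.23	5.47	15.95	7.32	5.17	6.76	1.98	0.43	4.20	0.20	2.71	1.17	1.58	2.39	3.18	1.72	1.03	2.96	3.57	0.00
Hyriopsis schlegelii	Hyriopsis	NC_015110	HQ641407	7.52	8.18	3.51	7.17	6.94	11.77	8.58	26.10	4.57	10.03	7.32	6.79	5.46	5.79	3.26	6.26	7.32	4.53	1.93	1.34	1.29	7.81	0.39	3.63	0.39	1.05	2.04	0.94	0.00	1.03	1.12	1.40	2.51
Meretrix lamarckii	Amarsipobranchia	KP244451	KP244452	49.65	55.03	37.86	27.41	61.65	43.82	45.83	59.95	45.08	51.38	41.22	52.56	51.58	58.08	40.76	70.81	62.34	37.47	38.34	19.57	13.55	9.71	12.95	43.17	15.42	17.81	4.82	13.75	18.90	9.93	16.90	33.45	28.73
Musculista senhousia	Amarsipobranchia	GU001953	GU001954	64.73	71.53	44.63	45.51	80.66		54.79	71.26	74.24	36.14	72.38	94.98	76.24	82.73	63.26	90.98	73.89	61.15	24.44	23.19	27.21		5.52	43.66	17.40	6.02	25.84	39.22	23.54	21.05	29.18	34.45	31.22
Mytilus californianus	Amarsipobranchia	GQ527172	GQ527173	86.82	90.97	73.94	76.00	97.13		61.28	93.29	78.24	79.71	75.76	89.64	106.51	124.15	127.89	105.55	135.27	77.64	69.09	39.82	35.96		11.87	35.05	21.50	26.53	35.36	72.89	46.92	43.94	49.80	79.85	79.85
Mytilus edulis	Amarsipobranchia	NC_006161	AY823623	62.25	71.85	39.72	32.36	73.33		60.52	64.70	68.87	62.87	72.10	79.52	82.80	80.57	88.82	75.66	82.04	43.20	35.14	16.66	17.47		4.70	11.60	9.24	19.40	14.85	27.86	12.17	16.85	16.94	20.60	56.50
Mytilus galloprovincialis	Amarsipobranchia	NC_006886	AY363687	64.68	73.22	45.18	36.47	74.60		53.95	76.90	69.80	67.62	77.26	92.88	38.73	82.16	87.21	81.51	83.56	45.76	44.43	15.20	14.86		4.50	10.66	11.91	15.28	16.07	25.51	4.44	22.44	16.42	22.26	25.29
Mytilus trossulus	Amarsipobranchia	HM462080	HM462081	65.35	75.63	36.44	36.82	67.12	99.83	55.70	70.59	75.06	66.15	71.69	78.44	89.01	85.48	97.43	91.61	90.81	37.64	34.79	19.12	13.84	67.99	5.86	12.11	12.61	13.61	14.24	27.31	19.65	22.44	17.58	46.48	23.50
Pyganodon grandis	Unionoidea	NC_013661	FJ809755	102.42	101.92	102.53	117.28	119.56	32.19	75.66	91.70	90.26	108.94	118.28	131.56	149.81	99.09	97.67	101.23	106.48	100.56	106.33	85.18	88.68	111.47	43.24	78.68	56.89	57.66	100.86	132.61	118.81	138.89	97.42	116.94	143.55
Quadrula quadrula	Unionoidea	NC_013658	FJ809751	113.61	115.31	100.34	113.18	83.49	377.36	76.67	83.03	84.97	108.53	97.81	112.58	87.45	80.06	120.22	92.09	125.57	109.20	88.44	84.23	88.77		40.23	62.47	61.38	52.44	93.92	141.42	79.85	223.27	109.69	103.39	175.18
Ruditapes philippinarum	Amarsipobranchia	NC_003354	AB065374	75.33	81.28	59.10	64.07	86.49		63.97	101.96	77.73	74.37	65.14	99.00	80.88	44.73	50.78	84.46	85.83	62.20	54.80	47.04	46.36		12.46	87.16	47.50	39.61	25.59	66.01	38.69	259.28	44.58	46.13	99.67
Solenaia carinatus	Unionoidea	NC_023250	KC848655	96.23	96.22	98.70	107.45	104.10	100.16	94.19	84.21	78.87	115.07	101.08	120.46	101.90	88.66	122.68	91.81	98.03	100.43	96.16	79.16	86.13	140.88	40.45	75.17	55.77	58.77	73.80	135.10	89.38	156.15	81.05	101.35	141.96
Utterbackia peninsularis	Unionoidea	HM856636	NC_015477	101.63	100.76	102.52	122.15	106.38	100.69	86.15	99.73	90.59	91.34	105.68	121.58	102.85	99.22	149.86	95.98	144.58	103.13	102.13	86.40	95.57	186.71	41.77	79.85	58.33	60.88	78.05	137.17	112.12	193.71	101.15	108.45	175.68
Venustaconcha ellipsiformis	Unionoidea	FJ809753	NC_013659	97.71	96.96	103.10	109.14	98.23	85.24	73.69	96.01	87.25	97.83	143.08	106.92	71.45	99.65	142.04	91.67	130.07	101.71	105.26	83.34	81.05	137.48	38.50	68.98	50.66	52.83	96.40	137.10	90.95	150.13	103.84	113.59	231.95
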