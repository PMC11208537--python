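sample_id	T-Cd	A-Cd	T-Cu	A-Cu	T-Pb	A-Pb	T-Zn	A-Zn	PLI
YX_1	1.62	0.95	8.53	4.64	35.81	6.13	33.59	2.39	1.51
YX_2	2.21	1.20	11.34	4.41	35.39	5.53	81.63	1.83	2.11
YX_3	0.46	0.19	25.37	9.40	61.76	9.09	82.58	4.07	2.07
YX_4	9.80	6.03	10.58	5.86	55.11	9.57	48.10	3.24	2.77
YX_5	0.78	0.34	8.41	3.09	28.62	3.47	35.76	2.67	1.21
YX_6	0.55	0.24	6.98	3.47	39.00	4.65	45.02	2.16	1.18
YX_7	4.01	1.38	13.59	3.57	42.94	4.06	67.27	2.01	2.64
YX_8	0.29	0.12	13.68	3.00	33.15	4.12	57.65	2.24	1.24
YX_9	0.30	0.11	10.39	4.85	38.17	4.69	46.16	2.23	1.13
YX_10	0.22	0.08	13.83	4.32	32.01	6.44	59.24	2.79	1.17
YX_11	0.31	0.11	14.72	4.96	39.78	5.98	59.24	1.71	1.32
YX_12	0.35	0.09	14.50	4.65	47.20	5.96	53.31	1.05	1.40
YX_13	0.23	0.09	14.74	6.69	33.76	5.98	70.01	2.97	1.23
YX_14	0.45	0.20	18.86	4.83	54.59	14.72	83.62	4.66	1.86
YX_15	0.37	0.18	13.19	4.58	37.66	8.84	63.63	2.66	1.37
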