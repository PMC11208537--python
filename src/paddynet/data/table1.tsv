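sample_id	som	ph	cec	ec	clay	silt	sand	tn	an	ap	ak
YX_1	30.22	4.97	6.17	111.41	19.45	31.30	49.25	1.84	112.22	68.50	75.67
YX_2	38.59	6.35	9.63	178.14	23.39	33.15	43.46	2.45	133.15	108.12	122.94
YX_3	52.32	5.75	14.83	132.06	28.88	36.18	34.94	2.87	189.53	196.85	117.32
YX_4	50.70	5.53	13.56	131.50	27.55	35.55	36.90	2.88	188.97	192.40	121.28
YX_5	27.00	5.46	6.54	81.57	20.17	31.55	48.28	1.63	132.52	71.47	76.47
YX_6	30.27	5.41	7.64	204.07	20.92	32.23	46.85	1.90	114.69	72.45	72.45
YX_7	33.60	5.23	8.79	114.13	22.39	32.94	44.66	2.01	127.69	86.38	78.46
YX_8	32.23	5.51	7.20	114.90	21.12	31.93	46.95	1.10	125.08	44.55	88.93
YX_9	40.92	5.25	9.26	165.93	23.49	33.21	43.30	1.03	170.29	58.41	94.49
YX_10	31.36	4.82	5.92	149.31	20.50	31.13	48.38	1.09	118.86	41.45	71.02
YX_11	29.87	5.41	9.22	140.46	22.46	33.20	44.34	1.06	121.43	43.49	95.69
YX_12	42.30	5.40	12.93	116.94	26.38	35.24	38.39	2.63	142.09	131.56	100.69
YX_13	31.18	5.54	8.57	86.24	23.39	32.73	43.88	2.20	135.26	97.23	82.82
YX_14	35.99	5.20	4.58	97.87	20.64	30.17	49.19	1.98	127.05	75.93	78.34
YX_15	41.42	5.59	6.92	85.62	21.22	31.79	46.99	2.68	166.65	144.18	83.39
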