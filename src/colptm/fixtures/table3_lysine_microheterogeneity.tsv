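# Micro-heterogenic occupancy (%) of O-glycosylated lysine sites in collagen I
# chains of zebrafish cardiac ECM across regeneration timepoints; mean +/- SEM.
# NA = not detected (ND). States: K (unmodified), HyK, G-HyK, GG-HyK.
# Detected-state means per (site, condition) sum to 100 +/- 0.1.
chain	site	state	sham_mean	sham_sem	dpa7_mean	dpa7_sem	dpa14_mean	dpa14_sem	dpa30_mean	dpa30_sem
COL1A1a	261	K	36.62	9.7	43.75	4.38	46.09	4.89	32.30	5.08
COL1A1a	261	HyK	38.38	10.38	34.81	12.3	21.13	2.85	45.72	8.65
COL1A1a	261	G-HyK	16.71	4.9	17.85	12.0	31.26	3.01	20.22	3.01
COL1A1a	261	GG-HyK	8.28	6.5	3.59	4.3	1.32	0.97	2.35	0.57
COL1A1a	270	K	50.46	5.3	32.92	4.4	26.58	1.7	46.48	4.1
COL1A1a	270	HyK	34.97	0.7	37.13	1.3	46.12	1.1	40.69	4.4
COL1A1a	270	G-HyK	12.26	5.0	29.03	4.4	24.56	2.7	11.52	0.4
COL1A1a	270	GG-HyK	2.32	1.1	0.93	1.3	2.74	0.2	1.30	0.7
COL1A1a	504	K	35.12	0.2	6.54	0.3	34.96	46.9	51.61	20.2
COL1A1a	504	HyK	7.20	4.4	3.49	0.3	16.03	22.4	16.85	5.2
COL1A1a	504	G-HyK	57.68	4.2	89.97	0.0	49.01	69.3	31.54	15.0
COL1A1a	504	GG-HyK	NA	NA	NA	NA	NA	NA	NA	NA
COL1A1a	570	K	59.52	12.5	24.79	15.4	17.67	1.6	42.84	51.5
COL1A1a	570	HyK	14.06	4.6	6.83	7.6	4.50	0.1	0.21	0.3
COL1A1a	570	G-HyK	NA	NA	NA	NA	NA	NA	NA	NA
COL1A1a	570	GG-HyK	26.42	17.1	68.39	7.8	77.83	1.6	56.95	51.8
COL1A1a	693	K	16.05	1.8	11.35	1.4	21.14	15.4	17.46	2.3
COL1A1a	693	HyK	73.86	2.2	83.40	0.1	70.60	23.8	74.25	1.7
COL1A1a	693	G-HyK	1.34	0.3	0.25	0.4	0.56	0.8	1.47	0.2
COL1A1a	693	GG-HyK	8.75	0.4	5.00	1.0	7.69	9.2	6.82	3.8
COL1A1a	846	K	NA	NA	NA	NA	NA	NA	NA	NA
COL1A1a	846	HyK	NA	NA	NA	NA	NA	NA	NA	NA
COL1A1a	846	G-HyK	48.69	29.7	85.04	19.4	51.02	9.0	68.87	5.5
COL1A1a	846	GG-HyK	51.31	29.7	14.96	19.4	48.98	9.0	31.13	5.5
COL1A1a	1017	K	62.44	0.3	33.69	22.8	52.55	21.8	60.09	0.5
COL1A1a	1017	HyK	34.82	0.4	62.96	20.9	36.95	22.1	24.44	0.2
COL1A1a	1017	G-HyK	NA	NA	NA	NA	NA	NA	NA	NA
COL1A1a	1017	GG-HyK	2.74	0.7	3.35	1.9	10.50	0.3	15.47	0.3
COL1A1b	264	K	50.52	15.5	40.63	50.7	52.94	15.8	20.39	20.2
COL1A1b	264	HyK	41.23	8.2	53.16	56.0	30.76	34.6	46.65	44.7
COL1A1b	264	G-HyK	5.19	4.4	4.64	3.6	9.75	10.8	27.51	20.7
COL1A1b	264	GG-HyK	3.05	2.9	1.57	1.6	6.54	7.9	5.45	3.7
COL1A1b	273	K	NA	NA	NA	NA	NA	NA	NA	NA
COL1A1b	273	HyK	41.65	47.5	50.93	39.7	24.43	25.6	33.90	36.0
COL1A1b	273	G-HyK	5.58	4.6	33.38	20.8	27.55	13.3	19.99	10.5
COL1A1b	273	GG-HyK	52.77	42.9	15.69	19.0	48.02	38.9	46.11	25.5
COL1A1b	849	K	27.06	1.1	10.35	13.7	11.17	2.2	22.95	3.4
COL1A1b	849	HyK	67.46	1.1	68.53	16.8	70.77	9.7	62.89	0.3
COL1A1b	849	G-HyK	3.35	0.4	6.76	9.4	12.97	4.5	9.48	1.5
COL1A1b	849	GG-HyK	2.13	0.4	14.36	12.4	5.09	2.9	4.68	2.2
COL1A2	254	K	6.48	3.2	20.75	14.6	21.61	14.3	55.69	18.4
COL1A2	254	HyK	89.24	1.6	78.24	13.4	69.76	2.2	43.90	18.1
COL1A2	254	G-HyK	0.11	0.0	0.10	0.1	0.22	0.3	0.05	0.0
COL1A2	254	GG-HyK	4.17	4.8	0.91	1.1	8.40	11.7	0.36	0.3
COL1A2	644	K	NA	NA	NA	NA	NA	NA	NA	NA
COL1A2	644	HyK	84.59	1.8	61.15	40.2	95.15	6.5	90.77	11.1
COL1A2	644	G-HyK	NA	NA	NA	NA	NA	NA	NA	NA
COL1A2	644	GG-HyK	15.41	1.8	38.85	40.2	4.85	6.5	9.23	11.1
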