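# Quantitative occupancy (%) of 3-hydroxyproline sites in collagen I chains
# (and one COL5A2a cluster) of zebrafish cardiac ECM across regeneration
# timepoints; mean +/- SD over biological replicates. "site" lists one or two
# (cluster) full-length proline positions joined by '+'.
chain	site	sham_mean	sham_sd	dpa7_mean	dpa7_sd	dpa14_mean	dpa14_sd	dpa30_mean	dpa30_sd
COL1A1a	707	7.55	4.3	31.49	38.1	21.21	7.8	20.50	1.5
COL1A1a	869	35.37	6.9	22.82	13.3	48.10	63.8	20.12	2.9
COL1A1a	878	28.87	7.2	17.57	18.4	27.63	35.8	12.76	1.8
COL1A1a	1148	48.73	14.7	44.03	17.0	68.96	41.1	7.23	4.6
COL5A2a	1195+1201	1.77	1.3	23.97	4.5	55.24	47.4	30.04	41.1
COL1A2	718	0.19	0.1	0.20	0.3	0.10	0.1	10.54	7.4
COL1A2	925	5.14	5.7	10.00	13.2	0.53	0.7	1.86	1.8
COL1A2	1066	3.92	3.4	3.87	3.1	12.95	15.7	6.91	2.0
COL1A2	361	0.96	0.3	1.52	1.6	4.66	4.5	1.18	0.4
COL1A1b	404	7.88	1.9	18.28	12.8	30.08	6.7	11.95	7.1
COL1A1b	554	47.73	4.0	46.52	14.8	76.14	29.7	42.91	1.3
COL1A1b	914	17.09	1.4	16.74	10.6	21.16	14.0	47.35	6.2
COL1A1b	1031	12.44	16.1	32.42	34.0	18.31	24.2	33.45	3.6
COL1A1b	1109	10.36	7.6	3.93	1.7	4.76	6.0	32.64	18.6
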