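# Published reference disproportionality statistics for the 50 drugs most
# strongly associated (by ROR) with drug-induced autoimmune-like hepatitis
# in FAERS, 2004Q1-2024Q1, as reported in the pharmacovigilance literature.
# Columns: canonical drug label, case count a, ROR with 95% CI, PRR with
# 95% CI, Yates chi-square, information component with lower credibility
# bound, EBGM with lower 95% bound.  Used as a desk-check input for the
# signal-classification rules; the underlying 2x2 cells are not public.
drug	a	ror	ror_lo	ror_hi	prr	prr_lo	prr_hi	chisq	ic	ic025	ebgm	ebgm05
nitrofurantoin	114	94.79	78.53	114.41	92.05	77.16	109.81	10065.79	6.5	6.23	90.24	77.09
minocycline	126	77.82	65.09	93.05	75.98	63.69	90.64	9120.48	6.22	5.96	74.33	64
elbasvir	3	47.12	15.06	147.39	46.42	15.19	141.87	133.31	5.54	4.11	46.4	17.87
fluvastatin	18	35.98	22.59	57.29	35.57	22.66	55.83	603.14	5.15	4.49	35.47	24.03
mogamulizumab	9	22.88	11.87	44.11	22.72	11.9	43.38	186.68	4.5	3.61	22.69	13.1
aldesleukin	4	22.06	8.25	59.01	21.91	8.22	58.38	79.81	4.45	3.18	21.9	9.61
propylthiouracil	4	21.75	8.13	58.18	21.61	8.11	57.58	78.59	4.43	3.16	21.59	9.48
hydralazine	21	20.44	13.3	31.42	20.31	13.2	31.26	384.34	4.34	3.73	20.24	14.13
ipilimumab	109	20.34	16.82	24.6	20.22	16.62	24.6	1953.7	4.31	4.04	19.85	16.93
cemiplimab	9	17.23	8.94	33.19	17.14	8.98	32.73	136.59	4.1	3.2	17.11	9.89
albendazole	5	16.88	7	40.66	16.79	6.95	40.56	74.2	4.07	2.91	16.78	8.04
nivolumab	311	16.24	14.48	18.21	16.17	14.38	18.19	4186.17	3.94	3.77	15.34	13.94
emtricitabine	3	15.95	5.13	49.61	15.87	5.09	49.46	41.79	3.99	2.57	15.86	6.14
metreleptin	5	15.57	6.46	37.5	15.5	6.42	37.44	67.76	3.95	2.79	15.48	7.42
efavirenz	24	15.44	10.33	23.08	15.37	10.39	22.75	321.14	3.94	3.37	15.31	10.94
meloxicam	25	14.33	9.67	21.24	14.27	9.64	21.12	307.22	3.83	3.27	14.21	10.22
atezolizumab	80	12.67	10.16	15.81	12.63	10.18	15.67	844.66	3.64	3.32	12.46	10.36
pembrolizumab	165	12.49	10.69	14.58	12.44	10.63	14.55	1686.89	3.6	3.38	12.11	10.64
atorvastatin	299	11.94	10.63	13.42	11.9	10.58	13.39	2831.22	3.5	3.33	11.33	10.28
simvastatin	101	11.47	9.42	13.97	11.43	9.4	13.9	944.77	3.49	3.21	11.25	9.54
olmesartan	50	11.46	8.67	15.14	11.42	8.68	15.03	471.36	3.5	3.1	11.33	8.97
fenofibrate	12	11.45	6.49	20.2	11.42	6.47	20.16	113.84	3.51	2.72	11.39	7.09
doxycycline	51	10.76	8.17	14.19	10.73	8.16	14.12	446.11	3.41	3.02	10.64	8.45
amoxicillin/clavulanic acid	24	10.55	7.06	15.77	10.52	7.11	15.57	205.96	3.39	2.82	10.48	7.49
interferon alfa-2b	55	10.01	7.67	13.06	9.98	7.59	13.13	440.17	3.31	2.93	9.89	7.92
ezetimibe	37	9.56	6.92	13.21	9.53	6.96	13.04	280.87	3.24	2.78	9.48	7.23
alemtuzumab	31	8.72	6.13	12.42	8.7	6.11	12.38	210.25	3.11	2.61	8.66	6.44
nefazodone	3	8.46	2.72	26.28	8.44	2.71	26.31	19.67	3.08	1.66	8.44	3.27
cephalexin	11	8.17	4.52	14.77	8.15	4.53	14.67	68.91	3.02	2.21	8.14	4.96
ribavirin	47	8.12	6.09	10.82	8.1	6.04	10.87	290.22	3.01	2.6	8.04	6.32
methylprednisolone	62	8.09	6.29	10.39	8.07	6.25	10.41	379.88	3	2.64	7.99	6.48
pravastatin	16	7.7	4.71	12.59	7.69	4.71	12.55	92.85	2.94	2.25	7.67	5.08
ketoprofen	3	7.23	2.33	22.47	7.22	2.32	22.5	16.07	2.85	1.43	7.22	2.8
methimazole	4	7.17	2.69	19.13	7.16	2.69	19.08	21.18	2.84	1.57	7.15	3.15
indomethacin	6	7.14	3.2	15.92	7.13	3.19	15.93	31.59	2.83	1.76	7.12	3.64
acitretin	5	6.97	2.9	16.78	6.96	2.88	16.81	25.5	2.8	1.64	6.95	3.34
terbinafine	19	6.91	4.4	10.85	6.9	4.4	10.83	95.54	2.78	2.15	6.88	4.72
onasemnogene abeparvovec-xioi	4	6.7	2.51	17.87	6.69	2.51	17.83	19.33	2.74	1.47	6.68	2.94
avelumab	4	6.46	2.42	17.24	6.45	2.42	17.19	18.42	2.69	1.42	6.45	2.84
anastrozole	29	6.38	4.43	9.2	6.37	4.39	9.24	130.74	2.67	2.15	6.35	4.67
darunavir	7	5.88	2.8	12.35	5.87	2.79	12.36	28.26	2.55	1.55	5.87	3.15
mesalazine	22	5.74	3.78	8.73	5.73	3.8	8.65	85.66	2.51	1.92	5.71	4.02
pemetrexed	21	5.67	3.69	8.71	5.66	3.68	8.71	80.31	2.5	1.89	5.64	3.94
interferon alfa-2a	58	5.65	4.36	7.31	5.64	4.37	7.28	219.04	2.48	2.11	5.59	4.5
durvalumab	17	5.55	3.45	8.94	5.54	3.46	8.87	63.13	2.47	1.8	5.53	3.71
daclizumab	4	5.3	1.99	14.13	5.29	1.99	14.09	13.91	2.4	1.14	5.29	2.33
rosuvastatin	72	5.27	4.18	6.65	5.26	4.16	6.65	245.56	2.38	2.05	5.21	4.29
irbesartan	13	5.25	3.04	9.04	5.24	3.03	9.07	44.5	2.39	1.63	5.23	3.32
bosentan	67	5.14	4.04	6.54	5.14	4.06	6.5	220.58	2.35	2	5.09	4.16
lamivudine	17	5.05	3.13	8.12	5.04	3.15	8.07	54.88	2.33	1.66	5.03	3.37
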