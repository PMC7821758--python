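gene	DMNC	MNC	Degree	EPC	BottleNeck	Closeness	Radiality	Betweenness	Stress
NUSAP1	1.0893	51	51	19.988	9	101.33333	5.09091	96.90787	1902
MCM3	0.91716	69	69	22.824	23	111.5	5.24242	372.309	7082
TRMT6	0.47733	9	11	2.093	6	69.78333	4.4	1264.09432	10640
RFC3	0.88611	60	60	20.772	10	107.25	5.19394	542.48026	7874
POLA2	1.16211	36	36	16.597	1	93.33333	4.97576	27.46845	786
AURKA	0.83591	71	71	23.302	7	112.5	5.25455	944.81247	9646
CDC20	0.75746	80	80	23.462	5	117.66667	5.33939	1556.30666	16426
TOP2A	0.81632	76	76	23.363	2	115.66667	5.30909	1108.53404	13048
ECT2	1.16516	30	30	14.084	1	89.33333	4.90303	9.41338	276
TK1	1.14366	41	41	17.127	1	95.75	5	60.29409	1056
MCM2	0.93961	69	69	22.807	5	111.58333	5.25455	827.49161	8772
FEN1	0.82386	73	73	22.298	4	114.25	5.29697	1278.36825	12488
NOP58	0.2704	15	16	2.45	10	76.91667	4.61818	2059.91502	14078
GINS2	1.15247	50	50	19.731	1	101	5.09091	105.79312	1852
NCAPD2	1.19618	38	39	17.413	7	96.25	5.05455	1216.19414	12076
KPNA2	0.97174	51	51	19.066	8	104.41667	5.21212	1504.41719	14138
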