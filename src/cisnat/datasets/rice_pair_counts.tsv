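chrom	transcripts	pairs	enclosed	convergent	divergent	CDS-p vs ncRNA	CDS-p vs CDS-n	CDS-p vs CDS-p	CDS-n vs ncRNA	CDS-n vs CDS-n	ncRNA vs ncRNA
1	10536	558	301	146	111	205	176	92	39	30	16
2	8527	440	239	115	86	159	141	63	36	30	11
3	9197	491	296	120	75	175	156	90	29	22	19
4	6762	361	185	95	81	100	132	55	27	27	20
5	5940	290	161	71	58	107	108	34	21	11	9
6	6166	299	170	69	60	111	100	38	23	13	14
7	5862	278	163	63	52	90	96	30	24	19	19
8	5290	239	138	51	50	103	74	27	19	10	6
9	4256	189	100	34	55	70	71	10	16	10	12
10	4144	221	128	41	52	85	74	24	19	10	9
11	4861	231	139	47	45	92	75	25	23	7	9
12	4472	222	129	46	47	81	72	24	20	15	10
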