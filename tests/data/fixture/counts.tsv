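gene	cancer_01	cancer_02	cancer_03	cancer_04	cancer_05	cancer_06	cancer_07	cancer_08	cancer_09	cancer_10	cancer_11	cancer_12	cancer_13	cancer_14	normal_01	normal_02	normal_03	normal_04	normal_05	normal_06	normal_07	normal_08
gene01	933	583	338	859	533	867	291	128	153	401	369	786	531	469	161	116	70	108	203	144	63	1241
gene02	1100	366	308	1189	305	1093	318	373	1087	351	497	163	376	304	86	374	137	200	101	178	144	158
gene03	1091	302	361	550	549	1174	341	433	227	455	151	125	434	229	225	158	44	140	278	80	230	174
gene04	727	432	812	957	316	801	258	389	501	325	874	932	461	618	150	71	64	96	154	103	448	148
gene05	396	494	393	973	55	2074	224	285	308	206	655	717	631	379	136	85	43	145	1407	81	82	144
gene06	60	20	30	36	23	91	26	29	38	35	33	37	85	46	36	44	36	43	48	95	26	71
gene07	25	9	1	8	16	25	8	10	47	15	15	21	14	13	28	19	5	16	24	21	19	35
gene08	65	13	23	42	17	96	35	30	42	41	31	30	46	33	56	34	34	48	47	75	40	106
gene09	826	497	244	699	152	668	196	299	537	374	202	219	253	272	430	225	174	588	508	450	303	308
gene10	41	29	7	17	15	36	9	10	23	23	13	14	14	12	21	16	4	18	18	6	22	30
gene11	13	2	3	22	9	31	4	17	19	12	10	21	7	13	17	12	14	23	19	16	8	19
gene12	7	4	3	6	9	12	3	3	17	5	2	5	2	8	10	7	6	4	13	2	0	8
gene13	479	448	277	564	295	915	167	400	469	436	330	595	569	536	539	667	246	579	1022	309	414	997
gene14	15	3	3	22	1	6	0	3	15	10	10	8	8	7	6	14	6	5	14	9	12	16
gene15	11	6	3	12	4	19	7	4	19	5	8	9	3	4	7	5	4	5	5	6	5	9
gene16	11	2	2	16	2	11	1	8	9	4	14	2	5	1	20	9	1	13	26	8	12	10
gene17	70	25	4	35	17	82	22	9	60	19	48	22	31	29	70	40	20	41	50	53	24	54
gene18	11	6	9	7	11	31	5	4	6	3	19	9	15	4	13	4	11	11	28	11	8	26
gene19	34	16	13	43	14	18	14	11	30	5	25	24	25	8	16	35	24	29	58	13	15	24
gene20	106	40	20	69	51	87	25	23	80	26	50	48	20	48	44	51	28	65	90	58	76	102
gene21	44	19	13	32	15	21	25	15	37	14	13	11	14	9	34	17	19	14	28	52	24	38
gene22	13	5	5	15	20	33	15	4	35	9	19	11	10	15	6	15	17	17	25	15	20	30
gene23	1417	132	449	1007	622	1674	253	327	836	432	552	1063	516	307	562	607	396	527	628	1007	764	1221
gene24	180	51	50	49	35	221	67	44	132	46	94	45	84	48	39	81	35	117	80	96	93	77
gene25	17	6	4	23	11	20	7	7	15	10	21	12	8	13	14	30	14	9	17	19	16	27
gene26	37	16	11	31	10	47	7	14	32	9	8	14	25	29	17	22	20	40	36	18	20	25
gene27	124	52	45	124	131	191	55	58	184	73	133	79	112	74	232	154	27	130	142	137	103	133
gene28	51	12	16	51	40	55	24	22	98	35	47	28	55	41	108	26	26	53	48	67	32	30
gene29	475	270	360	967	156	561	304	396	485	276	369	268	318	326	762	357	219	327	635	368	231	1261
gene30	23	10	9	29	12	30	4	8	14	13	34	12	12	14	24	17	8	19	6	11	14	47
gene31	189	141	75	167	107	264	116	63	273	111	193	87	166	84	253	185	79	179	420	243	230	164
gene32	134	52	18	184	21	150	28	43	117	50	68	32	51	57	105	70	29	87	141	83	40	196
gene33	6	5	5	15	5	15	4	12	17	9	16	16	13	14	20	13	15	10	23	27	16	20
gene34	419	118	121	216	140	598	134	165	272	137	221	244	217	173	521	378	170	456	406	308	307	550
gene35	73	9	21	56	39	103	22	26	67	47	42	62	83	41	89	60	32	60	57	85	63	70
gene36	5	1	3	12	4	4	4	5	5	3	7	10	5	6	6	8	7	11	3	7	4	11
gene37	13	5	5	9	5	23	10	7	10	2	17	12	13	4	22	13	7	15	12	15	18	11
gene38	155	49	45	89	135	184	18	89	118	54	50	140	106	58	200	83	43	107	70	147	127	219
gene39	28	13	6	41	19	45	11	30	27	21	39	40	47	20	34	31	15	30	53	34	30	60
gene40	356	158	106	195	98	560	171	182	443	192	279	205	438	139	407	203	178	246	431	187	200	446
gene41	275	26	52	170	125	200	75	100	181	98	73	116	122	104	109	139	96	153	225	147	191	136
gene42	242	188	122	348	93	638	93	115	312	99	312	176	298	196	381	188	83	446	260	397	120	356
gene43	5	5	4	3	11	21	2	3	16	14	6	15	2	7	6	8	6	8	18	21	8	13
gene44	90	35	39	198	80	101	28	61	109	50	68	73	123	116	148	65	55	95	163	84	83	58
gene45	113	97	86	135	98	266	56	97	245	66	142	108	162	60	181	120	45	189	233	103	75	201
gene46	79	23	32	55	22	69	11	16	35	27	38	51	47	29	48	42	18	53	111	115	46	91
gene47	8	7	0	12	3	9	3	5	11	3	9	8	17	14	10	11	2	8	15	4	8	8
gene48	10	6	5	7	14	9	6	6	8	6	6	4	6	3	14	7	8	7	7	15	18	7
gene49	314	188	365	222	295	831	121	216	607	245	395	346	227	170	378	307	125	553	508	313	240	242
gene50	13	7	3	9	5	16	0	9	4	4	5	16	14	3	14	11	2	15	12	8	6	12
gene51	49	16	23	88	20	38	20	16	27	22	30	19	54	21	25	14	7	46	31	45	40	35
gene52	56	19	14	20	20	35	6	22	32	21	19	11	42	15	18	19	16	38	37	45	44	40
gene53	11	4	2	13	4	9	2	0	12	4	5	5	4	6	9	8	4	2	3	7	6	3
gene54	379	177	297	428	407	477	205	127	999	472	486	517	254	238	502	664	278	444	628	338	354	861
gene55	324	152	158	430	235	490	87	156	337	136	213	192	337	295	282	221	194	227	241	242	239	204
gene56	11	6	7	5	6	21	4	2	2	4	6	10	0	2	5	6	2	4	6	1	7	5
gene57	80	55	21	110	31	123	53	58	162	31	142	45	57	100	75	34	34	78	74	73	107	148
gene58	23	7	6	26	9	14	4	7	19	6	14	11	14	11	24	15	12	17	17	10	10	15
gene59	135	92	98	295	165	376	107	114	250	99	164	193	120	243	106	230	108	300	197	276	256	297
gene60	443	135	102	357	342	677	203	212	324	155	185	186	215	264	771	337	140	476	656	263	302	391
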