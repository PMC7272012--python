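n	c_anhoej	l_anhoej	c_best	l_best	cbord	lbord	spec_anhoej	spec_best	spec_cut	sens_anhoej	sens_best	sens_cut
10	2	6	2	6	3	5	0.9551	0.9551	0.9375	0.3103	0.3103	0.3786
11	2	6	3	7	4	6	0.9512	0.9414	0.9297	0.3493	0.3887	0.4211
12	3	7	3	6	NA	NA	0.9570	0.9326	0.9326	0.3677	0.4392	0.4392
13	3	7	3	6	NA	NA	0.9634	0.9324	0.9324	0.3628	0.4519	0.4519
14	4	7	3	6	NA	NA	0.9395	0.9280	0.9280	0.4051	0.4740	0.4740
15	4	7	4	7	6	6	0.9495	0.9495	0.9260	0.4046	0.4046	0.4806
16	4	7	5	8	6	7	0.9533	0.9352	0.9288	0.4146	0.4800	0.4993
17	5	7	5	7	NA	NA	0.9353	0.9353	0.9353	0.5069	0.5069	0.5069
18	5	7	5	7	6	6	0.9415	0.9415	0.9320	0.5030	0.5030	0.5256
19	6	7	5	7	6	5	0.9212	0.9433	0.9276	0.5370	0.5078	0.5351
20	6	7	6	7	NA	NA	0.9294	0.9294	0.9294	0.5372	0.5372	0.5372
21	6	7	7	8	NA	NA	0.9328	0.9291	0.9291	0.5447	0.5672	0.5672
22	7	7	6	7	7	6	0.9173	0.9332	0.9273	0.6121	0.5573	0.5902
23	7	8	6	7	7	6	0.9520	0.9318	0.9277	0.5322	0.5728	0.5983
24	8	8	6	7	7	6	0.9338	0.9293	0.9266	0.5646	0.5900	0.6084
25	8	8	6	7	NA	NA	0.9439	0.9262	0.9262	0.5536	0.6077	0.6077
26	8	8	9	9	10	7	0.9500	0.9375	0.9265	0.5488	0.5986	0.6298
27	9	8	9	8	10	7	0.9358	0.9358	0.9295	0.6221	0.6221	0.6397
28	9	8	9	8	11	7	0.9431	0.9431	0.9302	0.6118	0.6118	0.6589
29	10	8	10	8	NA	NA	0.9277	0.9277	0.9277	0.6382	0.6382	0.6382
30	10	8	11	10	12	9	0.9360	0.9279	0.9258	0.6299	0.6533	0.6617
31	11	8	11	9	14	8	0.9197	0.9376	0.9256	0.6958	0.6515	0.6880
32	11	8	11	8	NA	NA	0.9289	0.9289	0.9289	0.6843	0.6843	0.6843
33	11	8	11	8	12	7	0.9348	0.9348	0.9298	0.6766	0.6766	0.6912
34	12	8	11	8	13	7	0.9218	0.9382	0.9278	0.6982	0.6724	0.7141
35	12	8	12	8	NA	NA	0.9285	0.9285	0.9285	0.6920	0.6920	0.6920
36	13	8	13	9	15	8	0.9148	0.9375	0.9291	0.7442	0.6966	0.7265
37	13	8	14	10	NA	NA	0.9222	0.9270	0.9270	0.7356	0.6940	0.6940
38	14	8	13	8	NA	NA	0.9078	0.9269	0.9269	0.7548	0.7298	0.7298
39	14	8	15	11	NA	NA	0.9158	0.9254	0.9254	0.7475	0.7308	0.7308
40	14	8	15	9	NA	NA	0.9212	0.9260	0.9260	0.7430	0.7509	0.7509
41	15	8	15	9	17	8	0.9095	0.9370	0.9287	0.7846	0.7353	0.7642
42	15	8	14	8	NA	NA	0.9154	0.9260	0.9260	0.7782	0.7408	0.7408
43	16	8	14	8	NA	NA	0.9032	0.9266	0.9266	0.7938	0.7427	0.7427
44	16	8	17	10	NA	NA	0.9096	0.9272	0.9272	0.7884	0.7704	0.7704
45	17	8	17	9	NA	NA	0.8969	0.9270	0.9270	0.8249	0.7815	0.7815
46	17	9	17	9	19	8	0.9361	0.9361	0.9281	0.7687	0.7687	0.7961
47	17	9	17	9	20	7	0.9428	0.9428	0.9260	0.7576	0.7576	0.8045
48	18	9	19	12	20	11	0.9317	0.9261	0.9255	0.7750	0.7863	0.7896
49	18	9	19	10	21	9	0.9388	0.9321	0.9271	0.7648	0.7928	0.8099
50	19	9	19	9	NA	NA	0.9272	0.9272	0.9272	0.8082	0.8082	0.8082
51	19	9	19	9	21	8	0.9348	0.9348	0.9271	0.7976	0.7976	0.8233
52	20	9	19	9	21	7	0.9228	0.9404	0.9293	0.8131	0.7885	0.8238
53	20	9	21	11	23	9	0.9308	0.9310	0.9258	0.8034	0.8120	0.8292
54	21	9	21	10	23	8	0.9183	0.9360	0.9270	0.8413	0.8130	0.8385
55	21	9	21	9	NA	NA	0.9268	0.9268	0.9268	0.8315	0.8315	0.8315
56	21	9	21	9	23	8	0.9331	0.9331	0.9259	0.8228	0.8228	0.8465
57	22	9	23	12	25	11	0.9228	0.9268	0.9254	0.8360	0.8341	0.8403
58	22	9	23	10	24	9	0.9295	0.9285	0.9260	0.8280	0.8441	0.8506
59	23	9	23	10	26	8	0.9188	0.9390	0.9275	0.8600	0.8312	0.8595
60	23	9	23	9	NA	NA	0.9258	0.9258	0.9258	0.8520	0.8520	0.8520
61	24	9	23	9	24	8	0.9148	0.9311	0.9282	0.8636	0.8448	0.8529
62	24	9	25	11	27	9	0.9222	0.9304	0.9250	0.8560	0.8552	0.8703
63	25	9	25	10	27	9	0.9108	0.9323	0.9273	0.8839	0.8588	0.8732
64	25	9	26	11	27	10	0.9185	0.9270	0.9256	0.8766	0.8558	0.8628
65	25	9	26	10	27	9	0.9244	0.9290	0.9266	0.8699	0.8606	0.8709
66	26	9	27	12	29	10	0.9149	0.9283	0.9254	0.8798	0.8701	0.8796
67	26	9	27	10	NA	NA	0.9210	0.9257	0.9257	0.8736	0.8820	0.8820
68	27	9	27	10	29	8	0.9112	0.9354	0.9267	0.8973	0.8720	0.8923
69	27	9	28	11	29	8	0.9177	0.9335	0.9253	0.8912	0.8669	0.8931
70	28	9	29	14	30	13	0.9076	0.9252	0.9250	0.8998	0.8830	0.8841
71	28	9	29	11	31	9	0.9143	0.9305	0.9251	0.8941	0.8878	0.9008
72	29	9	29	10	30	9	0.9040	0.9294	0.9271	0.9147	0.8927	0.8979
73	29	9	30	11	31	10	0.9109	0.9276	0.9262	0.9092	0.8882	0.8943
74	29	9	30	10	NA	NA	0.9163	0.9264	0.9264	0.9041	0.8941	0.8941
75	30	9	31	12	32	9	0.9076	0.9302	0.9254	0.9115	0.8978	0.9076
76	30	9	31	11	34	8	0.9132	0.9362	0.9252	0.9067	0.8961	0.9155
77	31	9	31	10	33	9	0.9042	0.9322	0.9274	0.9243	0.9025	0.9142
78	31	9	32	11	33	8	0.9100	0.9336	0.9255	0.9197	0.8966	0.9182
79	32	9	33	13	37	11	0.9009	0.9275	0.9251	0.9262	0.9094	0.9157
80	32	9	33	11	35	9	0.9069	0.9310	0.9255	0.9218	0.9126	0.9238
81	33	9	33	10	NA	NA	0.8975	0.9269	0.9269	0.9370	0.9181	0.9181
82	33	9	34	11	36	10	0.9038	0.9284	0.9254	0.9329	0.9129	0.9203
83	34	9	33	10	36	7	0.8942	0.9404	0.9263	0.9385	0.9048	0.9279
84	34	9	35	11	NA	NA	0.9006	0.9258	0.9258	0.9346	0.9266	0.9266
85	34	9	35	11	38	8	0.9057	0.9363	0.9253	0.9310	0.9189	0.9352
86	35	9	35	10	36	9	0.8975	0.9294	0.9273	0.9440	0.9254	0.9295
87	35	9	35	10	38	8	0.9027	0.9359	0.9255	0.9406	0.9196	0.9369
88	36	9	37	12	38	10	0.8944	0.9276	0.9253	0.9454	0.9319	0.9362
89	36	9	37	11	39	9	0.8998	0.9316	0.9261	0.9421	0.9317	0.9411
90	37	9	38	12	NA	NA	0.8913	0.9252	0.9252	0.9533	0.9318	0.9318
91	37	10	37	10	39	9	0.9314	0.9314	0.9268	0.9321	0.9321	0.9413
92	38	10	39	13	41	12	0.9221	0.9262	0.9254	0.9381	0.9389	0.9413
93	38	10	39	11	40	10	0.9291	0.9270	0.9255	0.9331	0.9425	0.9449
94	39	10	39	11	42	8	0.9196	0.9365	0.9256	0.9473	0.9365	0.9500
95	39	10	39	10	NA	NA	0.9268	0.9268	0.9268	0.9428	0.9428	0.9428
96	39	10	39	10	41	8	0.9327	0.9327	0.9254	0.9382	0.9382	0.9502
97	40	10	41	12	42	9	0.9246	0.9303	0.9254	0.9435	0.9459	0.9520
98	40	10	41	11	44	9	0.9306	0.9322	0.9251	0.9391	0.9464	0.9556
99	41	10	42	12	43	10	0.9223	0.9282	0.9259	0.9518	0.9457	0.9516
100	41	10	41	10	42	9	0.9285	0.9285	0.9265	0.9478	0.9478	0.9510
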