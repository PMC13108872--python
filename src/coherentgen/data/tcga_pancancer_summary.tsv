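cancer_type	total_samples	cna	rnaseq	rppa	wsi	complete	incomplete
BRCA	1224	1057	1214	919	1054	812	412
KIRC	610	521	606	477	513	442	168
UCEC	584	537	581	440	504	393	191
LUAD	581	507	577	365	468	310	271
HNSC	574	517	566	354	450	315	259
LUSC	555	497	551	328	477	301	254
PRAD	551	474	550	352	349	231	320
OV	530	494	380	385	101	50	480
LGG	530	520	530	435	493	400	130
GBM	523	498	154	218	338	42	481
COAD	503	447	501	363	432	331	172
STAD	478	429	448	357	347	255	223
SKCM	475	463	473	352	211	159	316
THCA	460	0	458	304	407	0	460
BLCA	432	403	425	343	299	244	188
LIHC	429	365	423	184	339	157	272
KIRP	324	284	323	216	262	190	134
CESC	312	296	309	172	196	121	191
SARC	267	247	264	226	224	181	86
TGCT	156	155	156	122	154	120	36
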