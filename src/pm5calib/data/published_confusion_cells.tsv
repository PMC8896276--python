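analysis	rule	tool	scope	tp	fn	fp	tn	plr	ci_low	ci_high
binary	a	-	combined	245	556	244	6496	8.4	7.2	9.9
binary	a	-	BRCA1	161	233	97	1316	5.9	4.7	7.4
binary	a	-	MSH2	84	323	147	5180	7.5	5.8	9.6
binary	b	-	combined	111	690	59	6681	15.8	11.6	21.4
binary	b	-	BRCA1	84	310	29	1384	10.3	6.8	15.4
binary	b	-	MSH2	27	380	30	5297	11.8	7.1	19.5
binary	c	REVEL	combined	122	679	52	6688	19.6	14.3	26.9
binary	c	REVEL	BRCA1	84	310	15	1398	19.5	11.5	33.2
binary	c	REVEL	MSH2	38	369	37	5290	13.4	8.6	20.8
binary	c	Meta-SNP	combined	145	656	29	6711	41.5	28.1	61.2
binary	c	Meta-SNP	BRCA1	99	295	9	1404	37.5	19.5	72.3
binary	c	Meta-SNP	MSH2	46	361	20	5307	29.6	17.8	49.3
binary	c	CADD	combined	154	647	77	6663	16.8	12.9	21.8
binary	c	CADD	BRCA1	109	285	37	1376	10.5	7.3	14.9
binary	c	CADD	MSH2	45	362	40	5287	14.7	9.7	22.1
binary	c	Grantham	combined	142	659	50	6690	23.7	17.4	32.4
binary	c	Grantham	BRCA1	90	304	20	1393	15.8	9.9	25.2
binary	c	Grantham	MSH2	52	355	30	5297	22.5	14.6	34.7
binary	c	aGVGD	combined	141	660	54	6686	21.8	16.1	29.6
binary	c	aGVGD	BRCA1	90	304	14	1399	22.3	13.0	38.5
binary	c	aGVGD	MSH2	51	356	40	5287	16.6	11.1	24.8
binary	c	BLOSUM45	combined	133	668	40	6700	27.7	19.6	39.1
binary	c	BLOSUM45	BRCA1	91	303	12	1401	26.2	14.7	46.8
binary	c	BLOSUM45	MSH2	42	365	28	5299	19.5	12.2	31.0
binary	c	BLOSUM62	combined	139	662	42	6698	27.6	19.7	38.6
binary	c	BLOSUM62	BRCA1	93	301	12	1401	26.8	15.0	47.8
binary	c	BLOSUM62	MSH2	46	361	30	5297	19.9	12.8	31.1
binary	c	BLOSUM80	combined	133	668	43	6697	25.8	18.5	36.0
binary	c	BLOSUM80	BRCA1	87	307	12	1401	25.1	14.0	44.8
binary	c	BLOSUM80	MSH2	46	361	31	5296	19.3	12.4	30.0
binary	d	REVEL	combined	69	732	15	6725	37.7	21.8	65.0
binary	d	REVEL	BRCA1	53	341	4	1409	42.6	16.4	110.7
binary	d	REVEL	MSH2	16	391	11	5316	18.7	8.9	39.5
binary	d	Meta-SNP	combined	81	720	6	6734	105.4	47.6	233.5
binary	d	Meta-SNP	BRCA1	62	332	4	1409	49.7	19.2	128.6
binary	d	Meta-SNP	MSH2	19	388	2	5325	101.9	27.4	378.6
binary	d	CADD	combined	86	715	28	6712	25.5	16.8	38.7
binary	d	CADD	BRCA1	68	326	16	1397	14.9	8.8	25.1
binary	d	CADD	MSH2	18	389	12	5315	19.3	9.5	39.3
binary	d	Grantham	combined	73	728	5	6735	112.3	47.4	266.3
binary	d	Grantham	BRCA1	52	342	2	1411	75.2	21.2	266.0
binary	d	Grantham	MSH2	21	386	3	5324	80.2	26.0	247.1
binary	d	aGVGD	combined	72	729	19	6721	31.3	19.1	51.2
binary	d	aGVGD	BRCA1	52	342	2	1411	75.2	21.2	266.0
binary	d	aGVGD	MSH2	20	387	17	5310	15.3	8.1	28.7
binary	d	BLOSUM45	combined	77	724	9	6731	68.6	35.1	134.0
binary	d	BLOSUM45	BRCA1	58	336	4	1409	46.5	18.0	120.6
binary	d	BLOSUM45	MSH2	19	388	5	5322	46.3	18.1	118.6
binary	d	BLOSUM62	combined	83	718	10	6730	66.8	35.3	126.5
binary	d	BLOSUM62	BRCA1	61	333	4	1409	48.9	18.9	126.6
binary	d	BLOSUM62	MSH2	22	385	6	5321	45.2	19.0	107.6
binary	d	BLOSUM80	combined	79	722	9	6731	70.3	36.0	137.3
binary	d	BLOSUM80	BRCA1	59	335	3	1410	60.9	20.8	177.8
binary	d	BLOSUM80	MSH2	20	387	6	5321	41.2	17.1	98.9
binary	e	REVEL	combined	42	759	7	6733	47.6	22.0	103.2
binary	e	REVEL	BRCA1	34	360	1	1412	82.3	16.1	420.6
binary	e	REVEL	MSH2	8	399	6	5321	17.1	6.2	47.2
binary	e	Meta-SNP	combined	49	752	3	6737	118.9	40.3	350.6
binary	e	Meta-SNP	BRCA1	36	358	2	1411	52.3	14.6	187.3
binary	e	Meta-SNP	MSH2	13	394	1	5326	117.5	21.8	633.1
binary	e	CADD	combined	52	749	17	6723	25.2	14.8	43.1
binary	e	CADD	BRCA1	43	351	11	1402	13.5	7.1	25.7
binary	e	CADD	MSH2	9	398	6	5321	19.1	7.1	51.5
binary	e	Grantham	combined	44	757	1	6739	249.4	49.1	1266.8
binary	e	Grantham	BRCA1	34	360	0	1413	247.0	15.2	4019.8
binary	e	Grantham	MSH2	10	397	1	5326	91.4	16.6	504.3
binary	e	aGVGD	combined	43	758	3	6737	104.5	35.2	309.6
binary	e	aGVGD	BRCA1	34	360	0	1413	247.0	15.2	4019.8
binary	e	aGVGD	MSH2	9	398	3	5324	35.4	10.5	120.2
binary	e	BLOSUM45	combined	49	752	4	6736	92.5	35.3	242.0
binary	e	BLOSUM45	BRCA1	41	353	0	1413	297.1	18.3	4819.2
binary	e	BLOSUM45	MSH2	8	399	4	5323	24.7	7.9	77.0
binary	e	BLOSUM62	combined	43	758	5	6735	66.5	27.5	160.9
binary	e	BLOSUM62	BRCA1	37	357	0	1413	268.5	16.5	4362.4
binary	e	BLOSUM62	MSH2	6	401	5	5322	15.4	5.0	47.8
binary	e	BLOSUM80	combined	46	755	6	6734	60.1	26.6	136.2
binary	e	BLOSUM80	BRCA1	39	355	1	1412	94.3	18.5	479.5
binary	e	BLOSUM80	MSH2	7	400	5	5322	17.8	6.0	53.3
banded	x	REVEL	combined	53	679	37	6688	13.1	8.7	19.7
banded	x	REVEL	BRCA1	31	310	11	1398	11.3	5.8	22.0
banded	x	REVEL	MSH2	22	369	26	5290	11.5	6.6	20.0
banded	x	Meta-SNP	combined	64	656	23	6711	25.6	16.1	40.9
banded	x	Meta-SNP	BRCA1	37	295	5	1404	28.9	11.9	70.1
banded	x	Meta-SNP	MSH2	27	361	18	5307	20.4	11.4	36.4
banded	x	CADD	combined	68	647	49	6663	13.0	9.1	18.5
banded	x	CADD	BRCA1	41	285	21	1376	8.3	5.0	13.7
banded	x	CADD	MSH2	27	362	28	5287	13.2	7.9	22.0
banded	x	Grantham	combined	69	659	45	6690	14.1	9.8	20.3
banded	x	Grantham	BRCA1	38	304	18	1393	8.6	5.0	14.7
banded	x	Grantham	MSH2	31	355	27	5297	15.8	9.6	26.0
banded	x	aGVGD	combined	69	660	35	6686	18.0	12.1	26.8
banded	x	aGVGD	BRCA1	38	304	12	1399	12.7	6.8	23.7
banded	x	aGVGD	MSH2	31	356	23	5287	18.3	10.9	31.0
banded	x	BLOSUM45	combined	56	668	31	6700	16.7	10.8	25.6
banded	x	BLOSUM45	BRCA1	33	303	8	1401	16.5	7.8	34.7
banded	x	BLOSUM45	MSH2	23	365	23	5299	13.7	7.8	24.0
banded	x	BLOSUM62	combined	56	662	32	6698	16.3	10.6	24.9
banded	x	BLOSUM62	BRCA1	32	301	8	1401	16.1	7.7	34.0
banded	x	BLOSUM62	MSH2	24	361	24	5297	13.8	8.0	23.9
banded	x	BLOSUM80	combined	54	668	34	6697	14.7	9.7	22.4
banded	x	BLOSUM80	BRCA1	28	307	9	1401	12.6	6.1	26.0
banded	x	BLOSUM80	MSH2	26	361	25	5296	14.3	8.4	24.3
banded	y	REVEL	combined	69	679	15	6688	40.1	23.3	69.2
banded	y	REVEL	BRCA1	53	310	4	1398	45.8	17.6	119.1
banded	y	REVEL	MSH2	16	369	11	5290	19.7	9.3	41.5
banded	y	Meta-SNP	combined	81	656	6	6711	114.1	51.5	252.8
banded	y	Meta-SNP	BRCA1	62	295	4	1404	54.7	21.1	141.3
banded	y	Meta-SNP	MSH2	19	361	2	5307	108.7	29.3	403.9
banded	y	CADD	combined	86	647	28	6663	27.7	18.2	42.0
banded	y	CADD	BRCA1	68	285	16	1376	16.3	9.7	27.6
banded	y	CADD	MSH2	18	362	12	5287	20.6	10.1	41.9
banded	y	Grantham	combined	86	647	28	6663	27.7	18.2	42.0
banded	y	Grantham	BRCA1	52	304	2	1393	82.1	23.2	290.5
banded	y	Grantham	MSH2	21	355	3	5297	86.4	28.0	266.0
banded	y	aGVGD	combined	72	660	19	6686	34.0	20.8	55.8
banded	y	aGVGD	BRCA1	52	304	2	1399	82.5	23.3	291.7
banded	y	aGVGD	MSH2	20	356	17	5287	16.5	8.8	30.9
banded	y	BLOSUM45	combined	77	668	9	6700	73.4	37.6	143.3
banded	y	BLOSUM45	BRCA1	58	303	4	1401	50.5	19.5	130.8
banded	y	BLOSUM45	MSH2	19	365	5	5299	48.9	19.1	125.1
banded	y	BLOSUM62	combined	83	662	10	6698	71.5	37.8	135.3
banded	y	BLOSUM62	BRCA1	61	301	4	1401	52.9	20.5	136.9
banded	y	BLOSUM62	MSH2	22	361	6	5297	47.8	20.1	113.7
banded	y	BLOSUM80	combined	79	668	9	6697	75.0	38.5	146.4
banded	y	BLOSUM80	BRCA1	59	307	3	1401	65.1	22.3	190.1
banded	y	BLOSUM80	MSH2	20	361	6	5296	43.8	18.2	105.1
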