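node_id	node_name	network	x	y	z	volume
1	Right postcentral gyrus	SM	41	-27	44.0	7312
2	Bilateral paracentral gyrus	SM	1.5	-13.9	43.5	4016
3	Left postcentral gyrus	SM	-38.6	-28.2	44.3	3752
4	Left superior temporal gyrus	AUD	-56.3	-2.3	-0.3	144
5	Right superior temporal gyrus	AUD	59.7	-3.4	-0.2	120
6	Left superior temporal gyrus	AUD	-60.8	-23.2	10.6	72
7	Thalamus/Caudate	TC	3.4	-24.9	-8.4	29552
8	Left culmen	TC	-15.7	-26.3	-29.3	208
9	Right anterior cingulate	ECN	1.7	33.3	13.3	18920
10	Left superior frontal gyrus	ECN	-26.4	44	19.2	5960
11	Right middle frontal gyrus	ECN	30.1	45.6	18.6	4696
12	Right caudate	ECN	15.4	16.3	0.8	728
13	Left caudate	ECN	-14.6	16	0.9	384
14	Bilateral thalamus	ECN	3.9	-11.4	4.3	1888
15	Bilateral posterior cingulate	DMN	1.2	-57	21.6	25376
16	Left middle temporal gyrus	DMN	-44.2	-64.7	24.6	3432
17	Right superior temporal gyrus	DMN	51.4	-59.1	19.7	2472
18	Bilateral anterior cingulate	DMN	2	50.7	-0.9	1984
19	Bilateral lingual gyrus	V1	2.1	-74.5	4.1	45072
20	Right inferior occipital gyrus	V2	42.4	-70.5	-3.1	10785
21	Left inferior occipital gyrus	V2	-39.2	-76.3	-2.5	5685
22	Bilateral lingual gyrus	V3	2.4	-88.8	-7.8	25952
23	Bilateral cuneus	V4	4.5	-88.3	22.4	12208
24	Left medial frontal gyrus	FRO	-10.9	26.3	-12.0	337
25	Right medial frontal gyrus	FRO	20.3	32.1	-13.5	519
26	Left middle frontal gyrus	FRO	-24.9	34.7	-14.1	73
27	Bilateral cerebellar tonsil/Culmen	CER	2.4	-45.5	-28.2	34938
28	Right culmen	CER	10.5	-36.1	-16.1	160
29	Left angular gyrus	FPL	-39.7	-57.7	37.1	17128
30	Left middle frontal gyrus	FPL	-42.3	25.7	22.0	13348
31	Left middle temporal gyrus	FPL	-58.2	-49.8	-9.5	577
32	Left cingulate gyrus	FPL	-4	22.8	37.3	152
33	Right supramarginal gyrus	FPR	51.8	-51.2	34.4	18758
34	Right middle frontal gyrus	FPR	46.1	23.8	27.6	10309
35	Right middle temporal gyrus	FPR	67	-40.8	-3.7	365
36	Right medial frontal gyrus	FPR	6.6	29.9	36.2	264
37	Bilateral medial frontal gyrus	HON1	-2.2	38.6	34.5	9556
38	Left inferior frontal gyrus	HON1	-45.9	24.9	-9.1	266
39	Left precuneus	HON2	0.4	-56.5	48.1	19104
40	Right inferior parietal lobule	HON2	60.3	-34.5	26.0	4480
41	Left inferior parietal lobule	HON2	-57.8	-37.2	27.1	3312
42	Left middle frontal gyrus	HON2	-30.2	35.8	29.5	1464
43	Right middle temporal gyrus	HON2	58.2	-58.4	1.4	542
44	Right middle frontal gyrus	HON2	32.8	42.4	25.0	448
45	Left inferior temporal gyrus	HON2	-53.2	-66	-0.4	163
46	Left middle occipital gyrus	HON2	-38.2	-82.7	20.8	88
47	Left cingulate gyrus	HON2	-10.8	-32.5	31.9	88
48	Right middle temporal gyrus	HON2	48.9	-72.7	14.4	72
49	Right precuneus	HON3	32.6	-70.2	33.3	8336
50	Left superior occipital gyrus	HON3	-29.8	-78.9	26.3	2736
51	Right posterior cingulate	HON3	15.4	-55.9	7.7	2048
52	Right middle frontal gyrus	HON3	28.8	8.3	47.5	368
53	Left precuneus	HON3	-9.2	-72.6	39.3	208
54	Left lingual gyrus	HON3	-10.7	-58	5.1	120
55	Right culmen	HON3	25.3	-38.3	-16.1	80
56	Left posterior cingulate	HON3	-15.9	-62.5	11.3	72
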