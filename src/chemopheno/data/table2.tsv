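id	name	S_hercynicus	S_ovatus	S_rupestris	J_pancicii	J_maritima
1	protocatechuic acid-O-hexoside	55.32	38.45	100	15.27	12.64
2	vanillic acid 4-O-hexoside	56.87	0	52.35	0	100
4	vanillic acid	66.47	84.99	100	0	0
5	protocatechuic acid	43.93	51.5	48.22	100	68.03
6	p-hydroxyphenylacetic acid-O-hexoside	36.05	68.05	100	0	0
8	syringic acid 4-O-hexoside	17.32	51.69	33.42	100	24.14
9	neochlorogenic acid	1.42	3.21	6.19	100	28.06
10	caffeic acid-O-hexoside	34.24	23.69	100	9.82	1.86
11	4-hydroxybenzoic acid-O-hexoside	32.1	50.1	100	0	15.24
12	esculetin-O-hexoside	45.48	100	24.71	19.44	12
13	4-hydroxybenzoic acid	60.25	46.55	100	42.4	71.02
15	ferulic acid-O-hexoside	18.03	70.66	100	0	0
16	gentisic acid	5.99	3.02	100	17.77	0
17	4-hydroxybenzoic acid-O-hexoside isomer	25.97	78.36	100	0	0
19	caffeic acid-O-hexoside	4.61	14.54	100	1.24	13.08
20	quinic acid	24.24	75.9	70.84	93.53	100
21	chlorogenic acid	28.47	77.32	71.97	94.47	100
22	caffeic acid-O-hexoside isomer I	48.92	44.77	100	38.53	18.62
23	4-caffeoylquinic acid	1.78	4.3	7.54	100	85.4
24	p-hydroxyphenylacetic acid	0	0	23.6	0	100
25	coumaric acid-O-hexoside	81.31	100	12.01	70.79	24.08
26	p-coumaric acid	83.38	100	12.42	73.49	25.08
27	caffeic acid	33.55	37.96	100	12.38	17.16
28	caffeic acid-O-hexoside isomer II	0	12.49	100	3.58	4.28
29	5-p-coumaroylquinic acid	26.13	63.12	18.11	31.1	100
30	3-hydroxy-dihydrocaffeoyl-5-caffeoylquinic acid	40.05	86.58	31.91	100	0
35	5-feruoylquinic acid	40.78	100	8.11	0	3.74
36	m-coumaric acid	49.92	41.24	100	0	68.8
37	3,4-dicaffeoylquinic acid	23.32	1.57	3.38	1.7	100
38	3,5-dicaffeoylquinic acid	9.21	59.82	95.36	51.54	100
39	1,5-dicaffeoylquinic acid	9.53	27.34	45.34	21.84	100
40	4,5-dicaffeoylquinic acid	4.14	14.58	33.42	31.87	100
42	salicilic acid	42.11	40.7	100	0	16.54
43	3-p-coumaroyl-5-caffeoylquinic acid	0	80.53	59.01	0	100
44	3-caffeoyl-5-p-coumaroylquinic acid	0	5.89	4.4	2.33	100
45	3-feruoyl-5-caffeoylquinic acid	16.99	100	13.26	0	17.99
46	3-caffeoyl-5-feruoylquinic acid	14.92	75.24	0	0	100
47	3,4,5-tricaffeoylquinic acid	0	3.95	7.03	0	100
48	6,8-di-C-hexosyl-naringenin	0	0	0	100	37.7
51	rutin	1.62	47.2	0.13	100	40.39
52	isorhamnetin-O-pentosylhexoside	0	100	0.64	65.54	12.03
53	isoquercitrin	1.19	81.87	29.95	22.06	100
54	quercetin 7-O-hexuronide	46.7	100	0.98	6.91	0
55	luteolin-O-hexuronide	35.07	100	0	0	0
56	kaempferol 7-O-rutinoside	1.89	58.25	0	100	39.27
57	quercetin 3-O-acetylhexoside	1.66	85.28	100	1.07	0
58	kaempferol-3-O-glucoside	0	63.53	100	0	0
59	isorhamnetin 3-O-glucoside	0.73	6.28	40.77	7.5	100
60	isorhamnetin-O-hexuronide	34.34	100	0	0	0
63	Quercetin	0	27.19	17.63	25.2	100
65	kaempferol	0	0	83.75	0	100
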