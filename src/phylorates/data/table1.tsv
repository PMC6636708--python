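family	dialects	n_sample	n_ethnologue	n_glottolog	root_age_yr	r_ethnologue_printed	doubling_ethnologue_printed	r_glottolog_printed	doubling_glottolog_printed	source
Kartvelian	0		5	6	5500	0.00029	2390	0.00032	2127	ref038
Dravidian	0		85	80	4500	0.00034	2039	0.00034	2056	ref073
Mayan	0		35	33	6500	0.00055	1260	0.00054	1288	ref039
Lezgic	1	20	9	10	3730	0.00059	1175	0.00062	1122	ref040
Inuit-Yupik	0		11	12	4000	0.0006	1155	0.00062	1115	ref038
Uralic	0	17	39	48	5300	0.00069	1005	0.00073	948	ref041
Indo-European	1	103	449	584	8700	0.0007	990	0.00073	946	ref018
Aslian	1		18	19	4000	0.00072	963	0.00074	941	ref042
Semitic	0	25	78	97	5614	0.00078	889	0.00081	850	ref043
Uto-Aztecan	0		61	69	5000	0.00082	845	0.00085	818	ref044
Japonic	1	59	12	15	2182	0.00114	608	0.00124	558	ref045
Bantu	0	409	668	721	4800	0.00136	510	0.00137	505	ref017
Austronesian	0	398	1268	1276	5230	0.00137	506	0.00137	506	ref016
Chapacuran	1	10	5	12	1039	0.00155	447	0.00239	289	ref046
Tupi-Guarani	0		51	48	2500	0.00157	441	0.00155	447	ref047
Chukchee-Kamchatkan	0		5	5	1000	0.00161	431	0.00161	430	ref038
Turkic	0	26	41	44	2206	0.00168	413	0.00172	404	ref048
Pama-Nyungan	0	306	285	248	5671	0.00099	695	0.00097	712	ref074
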