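population	label	region	HA	NI	PD	CS	CD	NF	NC	He	I	PL
Le Chasseron	LC	Switzerland	49600	31	0.0006	1455	96	26.67	14.27	0.141	0.217	48.38
Col de Roches	CR	Switzerland	12100	15	0.0012	181	155	0.07	0.00	0.093	0.144	34.09
Chruezflue	CF	Switzerland	3800	24	0.0063	2013	43	4.40	0.53	0.146	0.223	46.75
Balmfluechoepfli	BK	Switzerland	122100	18	0.0001	1526	80	0.13	0.00	0.152	0.235	52.92
Ravellen	RF	Switzerland	20300	27	0.0013	301	238	5.40	0.60	0.130	0.200	43.18
Braenten	BR	Switzerland	7900	16	0.0020	718	263	1.67	0.00	0.149	0.228	49.35
Holzflue	HF	Switzerland	95800	31	0.0003	1445	116	8.07	0.80	0.139	0.216	48.70
Geissflue	GE	Switzerland	21600	16	0.0007	510	138	1.20	0.00	0.154	0.236	50.65
Ruine Froburg	FB	Switzerland	6600	29	0.0044	1448	146	27.27	11.67	0.146	0.222	46.10
Saeliflue	SF	Switzerland	6300	21	0.0033	952	113	10.67	2.80	0.143	0.220	48.38
Schwedenleite	SL	Germany	9200	20	0.0022	518	1446	22.80	5.40	0.156	0.234	45.78
Fischleiten	FL	Germany	4400	60	0.0136	1932	2457	46.67	14.60	0.153	0.233	48.05
Rosskopf	RK	Germany	1900	23	0.0121	1783	1297	23.67	9.07	0.141	0.211	40.91
Kachelfels	KF	Germany	75	16	0.2133	857	957	11.20	2.80	0.167	0.249	47.40
Falkenhorst	FH	Germany	5800	61	0.0105	1522	1307	10.13	1.80	0.165	0.251	51.62
Schleuse	SE	Germany	7000	43	0.0061	2017	2306	5.80	1.20	0.152	0.233	50.65
Steinerbrueckl	SB	Germany	2400	12	0.0050	658	1465	5.33	1.83	0.134	0.200	38.64
Grain am Berg	GB	Germany	1900	23	0.0121	1385	1952	50.20	0.00	0.155	0.230	42.86
Achtel	AC	Germany	50	16	0.3200	1770	1560	31.33	0.40	0.119	0.174	30.84
Grundfelsen	GF	Germany	100	18	0.1800	1905	1246	0.87	0.00	0.107	0.157	27.27
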