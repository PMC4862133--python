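order	superfamily	st1_kb	st1_corrected_kb	j19_kb	j19_corrected_kb	mojavensis_kb
LTR	BelPao	435.35	1025.76	198.65	432.82	2255.95
LTR	Copia	309.80	522.62	162.75	275.82	718.71
LTR	ERVK	10.92	9.97	8.09	7.52	18.06
LTR	Gypsy	1610.37	3134.95	873.94	1334.42	6960.30
LINE	CR1	396.35	761.48	117.39	546.88	947.96
LINE	I	74.63	136.15	20.19	38.59	110.53
LINE	Jockey	478.24	600.72	246.54	345.78	765.64
LINE	L1	6.71	6.01	6.70	5.63	8.08
LINE	L2	191.37	213.18	145.73	148.74	395.99
LINE	LOA	1.18	1.31	0.82	0.65	1.95
LINE	R1	1383.35	1663.22	1011.77	1133.23	3721.30
LINE	R2	1.49	9.30	0.51	0.38	23.03
LINE	R4	1.57	0.80	0.70	0.57	1.37
LINE	RTE	6.76	9.55	0.69	0.68	1.43
TIR	hAT	563.03	661.13	239.06	414.90	654.13
TIR	Mutator	21.00	16.32	16.14	14.05	22.73
TIR	Novosib	17.35	16.43	11.89	10.77	16.15
TIR	P	590.70	830.17	216.28	713.43	752.39
TIR	PIF/Harbinger	3.81	9.71	2.21	2.45	7.82
TIR	piggyBack	18.67	9.46	5.38	5.79	77.21
TIR	Tc1/mariner	407.93	507.35	186.38	363.43	534.42
TIR	Transib	281.27	115.97	172.40	211.64	627.54
TIR	TIR other	113.23	310.35	69.75	84.18	55.43
Helitron	Helitron	5531.01	6331.89	1950.81	4689.50	10083.94
Maverick	Maverick	189.27	129.44	118.57	100.34	263.81
Others	Others	0.24	0.11	0.67	0.40	0.19
Unknown	Unknown	973.76	994.61	580.02	756.66	721.26
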