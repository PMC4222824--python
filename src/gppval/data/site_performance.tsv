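site_id	pft	ibis_r2	ibis_rmse	ibis_rpe	eclue_r2	eclue_rmse	eclue_rpe
CA-Oas	DBF	0.75	2.57	-32.34	0.87	2.26	26.75
DE-Hai	DBF	0.84	2.26	-17.92	0.88	1.62	-3.42
FR-Fon	DBF	0.68	2.98	-24.83	0.77	3.23	22.55
FR-Hes	DBF	0.74	3.07	-20.36	0.80	2.72	9.49
IT-Col	DBF	0.75	2.62	-18.94	0.75	2.88	20.36
IT-Ro1	DBF	0.61	2.03	6.49	0.77	2.33	32.39
IT-Ro2	DBF	0.24	4.05	-25.93	0.83	2.85	30.68
US-Bar	DBF	0.80	1.80	1.10	0.83	2.82	37.93
US-Bn2	DBF	0.72	1.12	10.49	0.86	1.04	14.97
US-Dk2	DBF	0.68	3.74	-23.88	0.81	2.86	19.87
US-Ha1	DBF	0.76	2.82	-19.57	0.82	2.38	11.84
US-MOz	DBF	0.32	3.62	-24.46	0.85	3.02	34.81
US-UMB	DBF	0.64	2.57	-2.44	0.92	2.47	41.20
US-Wi8	DBF	0.65	1.85	19.52	0.76	2.72	37.90
AU-Tum	EBF	0.69	2.80	22.60	0.75	2.27	-5.86
AU-Wac	EBF	0.43	2.92	24.27	0.39	2.66	5.82
FR-Pue	EBF	0.63	2.89	59.41	0.62	2.03	15.37
PT-Mi1	EBF	0.44	2.24	72.49	0.33	1.55	-17.23
CA-Ca3	ENF	0.74	1.38	14.26	0.76	1.87	14.11
CA-Man	ENF	0.94	0.61	6.83	0.80	1.19	13.54
CA-Obs	ENF	0.91	0.80	-11.11	0.86	1.16	9.49
CA-Ojp	ENF	0.88	0.77	17.75	0.78	0.99	5.13
CA-Qfo	ENF	0.84	0.91	4.25	0.80	1.19	9.92
CA-SJ3	ENF	0.79	1.24	33.48	0.75	2.12	51.35
FI-Hyy	ENF	0.87	1.43	-22.85	0.89	1.20	-2.87
FI-Sod	ENF	0.85	0.89	2.78	0.77	1.06	-7.73
IT-Ren	ENF	0.73	1.49	-7.29	0.69	1.74	-12.11
NL-Loo	ENF	0.81	2.28	-32.99	0.78	1.95	-21.84
RU-Fyo	ENF	0.87	2.30	-34.64	0.85	1.82	-23.40
RU-Zot	ENF	0.86	1.05	-14.51	0.85	1.00	0.63
SE-Fla	ENF	0.86	0.98	13.78	0.76	1.46	6.35
US-Bn1	ENF	0.75	0.99	6.62	0.76	1.10	1.76
US-Fmf	ENF	0.73	1.09	-14.31	0.73	1.50	21.17
US-Ha2	ENF	0.87	1.61	-21.33	0.85	1.96	11.45
US-Ho1	ENF	0.92	2.11	-31.29	0.84	1.69	-9.90
US-Me2	ENF	0.61	2.73	-47.52	0.77	1.63	-20.61
US-Me3	ENF	0.75	0.89	-6.74	0.76	1.15	-31.66
US-NC2	ENF	0.71	4.05	-42.25	0.83	2.08	6.32
CA-Let	GRA	0.84	1.68	-34.70	0.90	1.10	13.64
CN-HaM	GRA	0.82	1.68	-42.69	0.83	1.47	12.36
CN-Xi2	GRA	0.67	0.77	21.88	0.70	0.82	10.69
DE-Meh	GRA	0.84	1.90	-25.53	0.85	1.49	0.20
HU-Bug	GRA	0.70	1.92	-30.21	0.85	2.30	46.43
IE-Dri	GRA	0.65	2.80	-33.36	0.75	2.25	-6.00
IT-MBo	GRA	0.84	2.32	-28.74	0.83	2.49	20.46
PT-Mi2	GRA	0.76	1.43	-24.61	0.77	2.14	52.77
RU-Ha1	GRA	0.79	0.86	-3.50	0.82	1.77	42.51
US-ARc	GRA	0.64	2.91	-33.45	0.90	2.21	41.67
US-Aud	GRA	0.84	1.03	16.20	0.89	0.57	10.06
BE-Bra	MF	0.81	1.31	12.90	0.71	1.91	0.95
BE-Jal	MF	0.90	1.48	-19.78	0.84	1.99	-4.06
BE-Vie	MF	0.82	1.88	-25.86	0.78	2.10	-27.43
CA-Gro	MF	0.75	1.72	-7.45	0.75	3.07	44.54
JP-Tef	MF	0.54	2.29	0.07	0.61	2.33	9.86
JP-Tom	MF	0.78	3.48	-34.21	0.83	2.55	-21.88
US-PFa	MF	0.81	1.44	-0.10	0.76	2.50	28.45
ES-LMa	SAV	0.59	1.55	-39.30	0.77	1.27	8.16
ZA-Kru	SAV	0.32	2.10	-51.83	0.74	1.35	22.69
BW-Ma1	SAV	0.42	1.58	-48.15	0.74	0.90	9.73
US-FR2	SAV	0.11	2.17	-46.41	0.77	1.27	8.16
US-Ton	SAV	0.50	1.48	-20.37	0.79	2.14	31.26
US-SRM	SAV	0.59	1.49	4.82	0.66	1.88	25.23
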