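participant_id	sex	age_years	race	pack_years	smoking_status	fev1_liters	fev1_pct_predicted	fvc_liters	fvc_pct_predicted	fev1_fvc
P01	Female	25	White	0	Never	3.37	96	3.84	95	0.88
P02	Male	68	White	0	Never	4.96	109	6.20	114	0.80
P03	Female	61	White	0	Never	2.36	89	2.55	75	0.93
P04	Female	73	White	0	Never	1.94	93	2.21	84	0.88
P05	Female	59	White	0	Never	2.24	94	2.54	98	0.88
P06	Male	22	White	0	Never	4.62	100	5.92	106	0.78
P07	Female	24	Black	0	Never	2.72	82	2.98	82	0.91
P08	Male	53	White	0	Never	3.95	111	4.17	94	0.95
P09	Female	55	Black	20	Former	2.21	82	2.82	84	0.78
P10	Female	55	Black	20	Former	2.30	91	2.51	91	0.92
P11	Female	71	White	21	Former	1.72	85	1.97	79	0.88
P12	Male	58	White	48	Former	3.30	98	4.16	98	0.79
P13	Male	43	White	22.5	Current	4.41	119	5.34	116	0.83
P14	Female	59	White	10.5	Current	2.59	81	3.00	86	0.86
P15	Male	58	White	28.5	Current	3.50	89	4.59	95	0.76
P16	Male	53	White	10.5	Current	3.02	83	3.46	77	0.87
P17	Male	38	White	33	Current	4.74	108	5.63	106	0.84
P18	Male	63	White	35	Current	3.12	88	3.83	87	0.81
P19	Male	67	Black	25	Current	2.28	63	3.56	80	0.64
P20	Female	59	White	20	Current	1.38	53	2.00	60	0.69
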