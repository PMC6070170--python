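name	mature_seq	in_somniferum	in_bracteatum	au_pct	gc_pct	lp	mfe	mfei_printed
pso-miR1310	GGCAUCGGGGGCGUAACGCCCCU	1	1	40.51	59.49	80	-32.80	-0.68
pso-miR2911	GGCCGGGGGACGGGCUGGGA	1	1	27.37	72.63	95	-62.80	-0.91
pso-miR2910	UAGUUGGUGGAGCGAUUUGUC	1	1	52.54	47.46	59	-15.51	-0.55
pso-miR2916	UGGGGACUCGAAGACGAUCAUAU	1	1	47.83	52.17	98	-27.40	-0.53
pso-miR2914	CAUGGUGGUGACGGGUGACGGAG	1	1	47.62	52.38	63	-19.20	-0.58
pso-miR156h	UUGACAGAAGAUAGAGAGCAC	1	0	53.26	46.74	92	-44.30	-1.03
pso-miR172b	AGAAUCUUGAUGAUGCUGCAU	1	0	55.22	43.28	134	-41.70	-0.71
pso-miRf11320-akr	AAGAUGGAGAAGCAGGGCACGUGC	1	0	54.78	45.22	115	-38.10	-0.73
pso-miRf12412-akr	GCUGGGAUUACAGGCGUGAGCCACC	1	0	41.18	58.82	85	-28.50	-0.57
pso-miRf12256-akr	CACCAAAGGCCUCUGCCCUUC	1	1	42.19	57.81	64	-32.80	-0.88
pso-miR398b	UGUGUUCUCAGGUCGCCCCUG	1	0	54.55	45.45	99	-40.90	-0.90
pso-miR1122	UACUCCCUCCGUCCGAAAUUAUUU	1	1	64.71	35.29	85	-19.20	-0.64
pso-miR415	AACAGAGCAGAAACAGAA	1	1	69.41	30.59	85	-20.60	-0.79
pso-miR414	UCAUCUUCAUCAUCAUCGUCA	1	0	64.94	35.06	77	-14.20	-0.49
pso-miR5023	AUUGGUAGUGGAUAAGGGGGC	1	0	62.35	37.65	85	-21.30	-0.92
pso-miR1134	ACAACAACAACAAGAAGAA	1	0	72.94	27.06	85	-23.70	-0.66
pso-miR6485	UAGGAUGUAGAAGAGCAUAA	1	1	57.65	42.35	85	-19.30	-0.53
pso-miRf10082-akr	GGUGCAGGUGCAGGUGCAG	1	1	39.81	60.19	103	-52.10	-0.84
pso-miR168	UCGCUUGGUGCAGGUCGGGA	1	0	28.57	71.43	119	-67.70	-0.79
pbr-miR408	AUGCACUGCCUCUUCCCUGGC	0	1	49.41	50.59	85	-24.80	-0.57
pbr-miRf12309-akr	CACCAAAGGCCUCUGCCCUUC	0	1	45.88	54.12	85	-38.40	-0.83
pso-miR170	UGAUUGAGCCGUGCCAAUAUC	1	0	62.6	37.4	111	-40.90	-0.98
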