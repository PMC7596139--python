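subject	sex	age	duration_years	updrs_baseline	updrs_3mo	updrs_12mo	pdrp_baseline	pdrp_3mo	pdrp_12mo
1	F	50	8	49	21	60	3.01	0.11	1.83
2	M	66	19	62	53	69	1.61	-0.18	0.17
3	M	62	10	51	10	37	2.42	1.97	2.28
4	F	72	5	50	12	31	1.52	-0.40	0.39
5	M	53	17	39	30		4.21	2.84	
6	F	54	13	52	31		2.89	2.77	
7	F	77	7	51	24		3.71	2.53	
8	F	69	4	58	56		2.69	2.11	
9	M	65	6	35	10		0.72	0.26	
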