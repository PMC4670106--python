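# columns: sample_id	pmi	age_of_death	rin	age_of_onset	duration	cag	vonsattel_grade	hv_striatal	hv_cortical
sample_id	pmi	age_of_death	rin	age_of_onset	duration	cag	vonsattel_grade	hv_striatal	hv_cortical
H_0001	37.25	55	7.1	44	11	45	3	2.661	0.922
H_0002	5.75	69	7.5	63	6	41	3	2.644	1.081
H_0003	20.5	71	7.0	52	19	43	3	2.428	1.707
H_0005	19.15	48	6.9	25	23	48	4	3.820	1.939
H_0006	unk	40	6.2	34	6	51	4	3.522	1.431
H_0007	8	72	8.5	55	17	41	3	2.593	0.849
H_0008	21.3	43	7.4	28	15	49	3	2.701	1.701
H_0009	3.73	68	7.8	45	23	42	3	2.668	1.701
H_0010	6.16	59	8.3	35	24	46	3	2.621	1.200
H_0012	12.75	68	6.0	52	16	42	3	2.661	1.077
H_0013	25.1	57	6.1	40	17	49	3	2.911	1.491
H_0539	14.5	54	6.5	42	12	45	3	2.132	0.401
H_0657	24.3	61	8.1	36	25	45	4	3.290	1.604
H_0658	11	48	7.8	42	6	44	3	2.410	0.978
H_0681	19.06	69	7.0	50	19	42	3	2.484	1.088
H_0695	16.15	55	7.9	36	19	45	4	3.581	2.062
H_0700	15.66	50	8.0	33	17	47	3	2.741	1.202
H_0726	14.75	50	9.2	27	23	48	4	3.598	1.201
H_0740	13.58	75	6.4	60	15	42	3	2.621	2.361
H_0750	16.16	53	6.0	38	15	48	4	3.260	1.010
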