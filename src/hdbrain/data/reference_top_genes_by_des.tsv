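# columns: ensembl_id	symbol	overall_mean	hd_mean	control_mean	lfc	pvalue	padj	des
ensembl_id	symbol	overall_mean	hd_mean	control_mean	lfc	pvalue	padj	des
ENSG00000197971.10	MBP	180740.9	103940.8	212087.9	-1.14454	0.000227	0.003282	513821.5
ENSG00000131095.7	GFAP	139594.9	147197.9	136491.6	0.747036	0.001561	0.013498	194980.9
ENSG00000120885.15	CLU	98559.44	117016.8	91025.83	0.557853	0.000197	0.00296	139030.9
ENSG00000135821.11	GLUL	61547.89	76676.16	55373.08	0.671273	0.000218	0.003176	103210.9
ENSG00000104833.6	TUBB4A	20856.71	13003.3	24062.19	-0.84178	3.44E-08	4.12E-06	94539.22
ENSG00000171885.9	AQP4	20362.81	27513.91	17443.99	1.094429	2.29E-06	0.0001	89094.63
ENSG00000152661.7	GJA1	13340.95	19835.51	10690.11	1.263084	7.06E-08	6.94E-06	86931.93
ENSG00000168309.12	FAM107A	38970.09	47446.88	35510.18	0.737032	0.000164	0.002585	74321.76
ENSG00000134294.9	SLC38A2	5448.303	9251.666	3895.909	1.312784	3.02E-13	2.83E-10	68291.6
ENSG00000079215.9	SLC1A3	26782.89	35129.11	23376.27	0.855477	6.42E-05	0.001294	66171.29
ENSG00000198668.6	CALM1	83743.27	75824.67	86975.35	-0.34932	0.000542	0.006243	64492.7
ENSG00000160014.12	CALM3	47941.46	38247.79	51898.06	-0.55962	0.000424	0.005225	61221.65
ENSG00000124942.9	AHNAK	9570.149	14157.49	7697.765	1.190373	9.48E-08	8.73E-06	57631.07
ENSG00000226958.1	CTD-2328D6.1	16679.1	5983.11	21044.81	-1.19344	0.000217	0.003174	49731.65
ENSG00000154146.7	NRGN	39663.72	30172.8	43537.57	-0.69835	0.002654	0.019734	47221.27
ENSG00000007237.13	GAS7	15300.17	11322.25	16923.81	-0.69125	5.64E-07	3.50E-05	47122.17
ENSG00000078804.8	TP53INP2	6501.307	3430.574	7754.667	-1.37796	8.45E-08	8.02E-06	45652.02
ENSG00000180229.8	HERC2P3	1987.225	3987.18	1170.917	2.068673	8.09E-15	1.14E-11	44991.92
ENSG00000111674.3	ENO2	25831.65	20005.15	28209.81	-0.57404	6.29E-05	0.001273	42930.44
ENSG00000131711.10	MAP1B	37563.64	29736.15	40758.53	-0.51967	0.00057	0.006441	42770.9
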