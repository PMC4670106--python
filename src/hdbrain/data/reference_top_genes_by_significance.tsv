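# columns: ensembl_id	symbol	overall_mean	hd_mean	control_mean	lfc	pvalue	padj	des
ensembl_id	symbol	overall_mean	hd_mean	control_mean	lfc	pvalue	padj	des
ENSG00000069011.10	PITX1	5.645675	18.68429	0.323793	4.769658	9.57E-39	2.69E-34	903.9895
ENSG00000170689.8	HOXB9	2.542841	8.723281	0.020213	4.76079	1.63E-25	2.29E-21	249.8732
ENSG00000180818.4	HOXC10	2.801117	9.515088	0.060721	4.573976	2.91E-24	2.72E-20	250.6672
ENSG00000005073.5	HOXA11	1.968121	6.790017	0	4.704005	3.92E-24	2.75E-20	181.0905
ENSG00000253293.3	HOXA10	3.490951	11.39924	0.263077	4.273311	8.03E-24	4.51E-20	288.5972
ENSG00000128710.5	HOXD10	2.571228	8.771584	0.040471	4.602451	1.35E-23	6.33E-20	227.1957
ENSG00000151615.3	POU4F2	3.275095	10.65475	0.262991	3.962235	3.42E-23	1.37E-19	244.7754
ENSG00000106031.6	HOXA13	2.456714	8.029653	0.182045	4.165899	6.20E-23	2.18E-19	190.9965
ENSG00000128709.10	HOXD9	2.226869	7.18692	0.202358	3.657288	1.22E-18	3.80E-15	117.4429
ENSG00000175879.7	HOXD8	1.709838	5.601477	0.121413	3.86684	2.09E-18	5.88E-15	94.09001
ENSG00000152779.12	SLC16A12	55.42204	167.6664	9.608012	3.513877	4.74E-18	1.11E-14	2717.727
ENSG00000106004.4	HOXA5	2.198025	7.087533	0.202308	3.879624	4.49E-18	1.11E-14	119.0033
ENSG00000113196.2	HAND1	1.939326	6.244745	0.182012	3.703297	1.46E-17	3.16E-14	96.95744
ENSG00000171540.6	OTP	3.20356	9.16907	0.768658	2.998538	3.93E-17	7.88E-14	125.8704
ENSG00000056736.5	IL17RB	1311.101	2144.334	971.0062	1.392757	3.80E-16	7.12E-13	22182.16
ENSG00000163817.11	SLC6A20	173.0366	433.2822	66.81386	2.355393	2.49E-15	4.37E-12	4629.918
ENSG00000197757.7	HOXC6	1.32181	4.411567	0.060685	3.608891	4.26E-15	7.04E-12	53.19922
ENSG00000183943.5	PRKX	604.7496	900.2916	484.1202	1.419149	6.22E-15	9.20E-12	9471.658
ENSG00000112303.9	VNN2	25.7452	62.90119	10.57949	2.490891	6.03E-15	9.20E-12	707.7395
ENSG00000180229.8	HERC2P3	1987.225	3987.18	1170.917	2.068673	8.09E-15	1.14E-11	44991.92
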