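snp_id	genes	disease	risk_allele	risk_decreases_with_delta	kendall_p	tau_rank	fst_rank_biaka_orcadian	fst_rank_biaka_maya	lnrsb_rank_ceph	lnrsb_rank_chbjpt	circadian_connection
rs1930961	LRP5L;ADRBK2	BPD	C	Yes	1.182e-6	0.993	0.996	0.942	0.530	0.700	ADRBK2 (GRK3) phosphorylates melanopsin
rs6746896	LMAN2L;CNNM4	BPD	A	Yes	8.421e-7	0.995	0.550	0.350	0.780	0.790	CNNM4 is an RNAi hit
rs8099939	GRIK5	BPD	T	Yes	6.538e-5	0.956	0.968	0.615	0.960	0.980	-
rs2286492	FAM126A	BPD	G	No	8.521e-5	0.966	0.811	0.000	0.160	0.260	-
rs7570682	TMEM18;POU3F3	BPD	A	Yes	2.320e-4	0.950	0.455	0.004	0.160	0.090	-
rs4075511	KCNS3;RDH14	BPD	A	No	7.345e-9	0.999	0.797	0.156	0.720	0.730	-
rs7319311	COL4A2	BPD and SCZ	A	No	1.083e-4	0.952	0.474	0.319	0.400	0.470	Clock-regulated in mouse cardiomyocytes
rs1124376	KAT2B	BPD and SCZ	G	Yes	3.852e-4	0.950	0.860	0.076	0.880	0.150	Directly interacts with CLOCK and NPAS2
rs1605834	APOB;KLHL29	BPD and SCZ	C	Yes	2.857e-4	0.950	0.966	0.877	0.350	0.240	-
rs17002034	MKL1	BPD and SCZ	G	Yes	2.322e-5	0.978	0.689	0.000	0.990	0.990	RNAi hit
rs589249	CSF3R;GRIK3	SCZ	G	Yes	4.565e-5	0.964	0.996	0.624	1.000	1.000	Grik3 expression is Clock-regulated in mouse VTA
rs7004633	MMP16;RIPK2	SCZ	A	No	1.433e-6	0.992	0.925	0.538	0.260	0.330	-
rs1009080	PTPRU;MATN1	SCZ	G	Yes	2.419e-6	0.988	0.987	0.708	0.900	0.690	-
rs1572299	TLR4;DBC1	SCZ	A	Yes	3.901e-4	0.951	0.950	0.321	1.000	0.200	DBC1 regulates NR1D1 stability
rs892055	RASGRP4	Asperger	nr	na	4.268e-5	0.964	0.603	0.585	0.610	0.420	-
rs9601248	NDFIP2;SPRY2	MDD	C	No	7.198e-5	0.958	0.896	0.085	0.390	0.330	SPRY2 is a direct ARNTL target in mouse liver
rs8020095	GPHN	Depression	A	Yes	1.273e-4	0.950	0.944	0.504	0.620	0.980	GPHN shows rhythmic expression in mouse SCN
rs12593813	MAP2K5	RLS	A	No	2.066e-5	0.971	0.498	0.175	1.000	0.830	-
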