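snp_id	gene	gene_set	kendall_p	tau_rank	fst_rank_biaka_orcadian	fst_rank_biaka_maya	lnrsb_rank_ceph	lnrsb_rank_chbjpt	annotation
rs11048980	ARNTL2	core_circadian	7.167e-8	1.000	0.506	0.000	0.79	0.89	intronic
rs6811520	CLOCK	core_circadian	1.444e-5	0.978	0.831	0.466	0.84	0.87	intronic
rs11038695	CRY2	core_circadian	1.626e-4	0.957	0.624	0.247	0.64	0.33	intronic; in LD (r2=0.93 in CEPH) with rs11038697
rs4789846	CSNK1D	core_circadian	5.546e-5	0.970	0.601	0.000	0.69	0.84	intronic
rs5995572	CSNK1E	core_circadian	1.053e-5	0.984	0.973	0.515	0.05	0.14	intronic
rs17654772	NPAS2	core_circadian	2.549e-7	0.998	0.615	0.377	0.84	0.43	intronic
rs4663868	PER2	core_circadian	9.462e-5	0.962	0.286	0.219	0.97	0.90	intronic
rs2583836	ABL1	rnai_hits	3.071e-7	0.995	0.936	0.311	0.97	0.63	intronic
rs12713670	ANTXR1	rnai_hits	4.331e-9	1.000	0.108	0.468	0.57	0.58	intronic
rs12193789	ASCC3	rnai_hits	9.351e-6	0.994	0.371	0.166	0.94	0.96	intronic
rs11581556	ATF6	rnai_hits	7.326e-7	0.995	0.845	0.615	0.96	0.90	intronic
rs5996513	BCR	rnai_hits	8.368e-6	0.996	0.932	0.626	0.11	0.21	intronic
rs8	CDK6	rnai_hits	9.581e-7	0.998	0.800	0.299	0.82	0.85	intronic
rs2304593	CMTM7	rnai_hits	5.239e-6	0.993	0.370	0.000	0.16	0.34	intronic
rs2279103	CTDP1	rnai_hits	6.403e-8	0.999	0.745	0.276	0.70	0.50	missense T340M
rs657801	DENND2D	rnai_hits	9.280e-6	0.983	0.797	0.352	0.94	0.94	intronic
rs2354420	EMP2	rnai_hits	6.654e-6	0.988	0.657	0.167	0.08	0.18	intronic
rs11792480	ENG	rnai_hits	1.281e-5	0.989	0.954	0.041	0.83	0.68	intronic
rs550897	FAM55D	rnai_hits	3.670e-8	0.998	0.848	0.308	0.99	0.99	missense Y398H
rs1011814	FGF10	rnai_hits	6.501e-7	0.994	0.926	0.513	0.99	1.00	intronic
rs17679400	FHIT	rnai_hits	1.3645e-7	0.998	0.742	0.255	0.26	0.20	intronic
rs1416995	GPR158	rnai_hits	2.921e-7	0.997	0.995	0.973	0.04	0.29	intronic
rs12787863	GRM5	rnai_hits	3.597e-7	0.996	0.860	0.088	0.94	0.81	intronic
rs17422	HCFC1	rnai_hits	1.623e-7	0.997	0.936	0.004	0.84	0.81	intronic
rs11586100	HNRNPR	rnai_hits	4.271e-6	0.984	0.968	0.248	1.00	1.00	intronic
rs1122821	HOMER3	rnai_hits	8.660e-6	0.980	0.479	0.013	0.46	0.61	intronic
rs2158622	JAZF1	rnai_hits	5.810e-6	0.991	0.716	0.000	0.04	0.49	intronic
rs9952025	LIPG	rnai_hits	1.269e-5	0.994	0.764	0.787	0.18	0.11	intronic
rs955816	MARCH4	rnai_hits	1.735e-6	0.991	0.910	0.186	0.85	0.37	intronic; in LD (r2=0.80 in CHB+JPT) with rs11691655
rs566125	MMP3	rnai_hits	1.247e-6	0.995	0.716	0.254	0.98	0.96	intronic
rs710080	MPG	rnai_hits	1.641e-7	0.998	0.989	0.840	0.44	0.54	5' UTR variant
rs1053000	PFKP	rnai_hits	9.234e-6	0.988	0.971	0.152	1.00	1.00	3' UTR variant
rs578096	PTGER3	rnai_hits	1.272e-5	0.985	0.733	0.000	0.77	0.51	intronic
rs2020945	PWP2	rnai_hits	5.640e-8	0.998	0.965	0.780	0.62	0.50	missense D25N
rs11617401	RAB20	rnai_hits	5.288e-7	0.997	0.791	0.000	0.89	0.47	intronic
rs1204897	RCC2	rnai_hits	7.331e-6	0.987	0.540	0.496	0.37	0.46	intronic
rs17682132	RCVRN	rnai_hits	3.072e-7	0.998	0.943	0.000	0.96	0.33	intronic
rs492786	SCARA3	rnai_hits	7.034e-6	0.982	0.197	0.417	0.82	0.68	intronic
rs9812406	SCHIP1	rnai_hits	1.487e-7	0.998	0.989	0.577	0.60	0.68	intronic
rs6695715	SEC16B	rnai_hits	1.113e-5	0.982	0.247	0.123	0.44	0.78	intronic
rs2224957	SH3GL2	rnai_hits	2.399e-7	0.996	0.896	0.180	0.01	0.04	intronic
rs6081636	SLC24A3	rnai_hits	5.980e-6	0.988	0.612	0.246	0.16	0.47	intronic
rs830142	SLC8A2	rnai_hits	7.264e-6	0.993	0.325	0.000	0.67	0.80	intronic
rs732611	TBC1D9	rnai_hits	4.321e-8	0.999	0.943	0.000	0.78	0.87	intronic
rs1514685	TPO	rnai_hits	5.156e-8	0.998	0.720	0.199	0.23	0.17	intronic
rs11760463	WDR86	rnai_hits	1.279e-5	0.975	0.854	0.378	1.00	0.97	intronic
rs10227271	WNT2	rnai_hits	6.406e-6	0.983	0.971	0.173	0.07	0.70	intronic
rs3753472	ADORA1	mouse_circadian	1.155e-5	0.981	0.941	0.445	0.80	0.21	intronic
rs2830044	APP	mouse_circadian	5.206e-6	0.985	0.833	0.311	0.53	0.71	intronic
rs228188	BTBD9	mouse_circadian	3.149e-6	0.993	0.895	0.155	1.00	0.72	intronic
rs7801807	CADPS2	mouse_circadian	1.465e-5	0.993	0.891	0.000	0.90	0.90	intronic
rs17818083	EBF2	mouse_circadian	2.924e-6	0.992	0.939	0.000	0.11	0.24	intronic
rs809192	FYN	mouse_circadian	1.270e-5	0.987	0.804	0.061	0.82	0.63	intronic
rs2134294	HCRTR2	mouse_circadian	5.923e-6	0.986	0.741	0.405	1.00	0.96	intronic
rs17187747	KCNB2	mouse_circadian	6.700e-7	0.994	0.652	0.349	0.33	0.54	intronic
rs12762512	KCNMA1	mouse_circadian	4.857e-8	0.999	0.307	0.494	0.29	0.33	intronic
rs1943620	NCAM1	mouse_circadian	9.774e-9	0.999	0.838	0.410	0.18	0.19	intronic
rs10774910	NOS1	mouse_circadian	1.693e-6	0.990	0.916	0.118	1.00	1.00	intronic
rs2294678	NOX3	mouse_circadian	1.530e-5	0.980	0.950	0.172	0.18	0.87	intronic
rs12043436	OMA1	mouse_circadian	2.192e-6	0.991	0.840	0.129	0.99	0.95	intronic
rs595146	PHLPP1	mouse_circadian	8.637e-6	0.999	0.877	0.000	0.34	0.29	intronic
rs10508958	PRKG1	mouse_circadian	4.490e-7	0.996	0.873	0.193	0.99	0.69	intronic
rs3733553	PRKG2	mouse_circadian	1.212e-5	0.980	0.868	0.823	0.96	0.99	intronic
rs752579	RAI1	mouse_circadian	1.023e-5	0.981	0.954	0.473	1.00	0.96	intronic
rs2271733	RAX	mouse_circadian	1.464e-5	0.984	0.688	0.443	0.89	0.63	missense D44E
rs10519052	RORA	mouse_circadian	3.667e-6	0.991	0.448	0.234	0.68	0.68	intronic
rs968357	RORB	mouse_circadian	2.655e-6	0.992	0.755	0.560	0.63	0.83	intronic
rs2236409	TNC	mouse_circadian	9.344e-6	0.985	0.455	0.063	0.40	0.96	intronic
rs7300641	TPH2	mouse_circadian	1.676e-5	0.975	0.827	0.400	0.01	0.02	intronic
rs4445877	UBE3A	mouse_circadian	1.849e-5	0.974	0.939	0.607	0.90	0.99	intronic
rs5909187	CDKL5	human_sleep	6.275e-6	0.987	0.550	0.017	0.27	0.55	intronic
rs11603330	DHCR7	human_sleep	2.848e-7	0.995	0.806	0.479	0.75	0.98	intronic
rs13414769	HDAC4	human_sleep	3.134e-5	0.969	0.573	0.264	0.94	0.98	intronic
rs2239464	MECP2	human_sleep	3.189e-7	0.996	0.663	0.517	0.48	0.28	intronic
rs858953	NRXN1	human_sleep	1.226e-9	1.000	0.780	0.254	0.83	0.49	intronic
rs8137951	SHANK3	human_sleep	3.148e-6	0.989	0.517	0.127	0.59	0.44	intronic
rs12406072	SLC2A1	human_sleep	2.430e-5	0.980	0.952	0.518	0.56	0.52	intronic
rs308039	GNA11	melanopsin	2.387e-5	0.972	0.568	0.079	0.06	0.29	intronic
rs4745672	GNAQ	melanopsin	4.391e-6	0.986	0.790	0.610	1.00	0.92	intronic
rs2476197	INADL	melanopsin	1.834e-7	0.998	0.943	0.252	0.92	0.96	intronic
rs2224361	PLCB4	melanopsin	4.222e-5	0.991	0.426	0.000	0.32	0.37	intronic
rs2138004	PRKCA	melanopsin	3.025e-5	0.971	0.974	0.708	0.24	0.33	intronic
rs10910030	PRKCZ	melanopsin	1.588e-8	0.999	0.771	0.234	0.18	0.27	intronic
rs1392171	TRPC7	melanopsin	2.123e-6	0.993	0.371	0.000	0.48	0.70	intronic
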