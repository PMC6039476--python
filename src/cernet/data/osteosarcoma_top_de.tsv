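contrast	rna_class	id	pvalue	log2fc
primary_vs_control	miRNA	miR-2682-5p	0.002005	8.66
primary_vs_control	miRNA	miR-4435	0.009722	7.08
primary_vs_control	miRNA	miR-181b-3p	6.99E-05	7.05
primary_vs_control	miRNA	miR-138-1-3p	0.006732	6.59
primary_vs_control	miRNA	miR-4741	0.002851	6.39
primary_vs_control	miRNA	miR-4421	0.005265	6.29
primary_vs_control	miRNA	miR-940	0.000135	5.76
primary_vs_control	miRNA	miR-224-5p	0.002128	5.66
primary_vs_control	miRNA	miR-222-3p	6.87E-05	5.58
primary_vs_control	miRNA	miR-203a-3p	0.009058	5.58
primary_vs_control	miRNA	miR-1-3p	1.80E-38	-10.5
primary_vs_control	miRNA	miR-133a-3p	4.54E-43	-10.19
primary_vs_control	miRNA	miR-208b-3p	2.10E-14	-9.9
primary_vs_control	miRNA	miR-206	1.10E-20	-9.5
primary_vs_control	miRNA	miR-133a-5p	3.16E-20	-9.46
primary_vs_control	miRNA	miR-499a-5p	2.85E-16	-9
primary_vs_control	miRNA	miR-95-5p	2.10E-07	-8.8
primary_vs_control	miRNA	miR-128-2-5p	2.03E-05	-7.55
primary_vs_control	miRNA	miR-6505-5p	6.41E-08	-7.05
primary_vs_control	miRNA	miR-520b	0.008803	-5.3
primary_vs_control	lncRNA	AC112721.2	5.00E-05	7.76
primary_vs_control	lncRNA	AL096865.1	5.00E-05	6.82
primary_vs_control	lncRNA	LOC100129940	5.00E-05	6.74
primary_vs_control	lncRNA	AC005277.1	5.00E-05	6.23
primary_vs_control	lncRNA	AC092484.1	5.00E-05	6.11
primary_vs_control	lncRNA	APCDD1L-DT	5.00E-05	5.86
primary_vs_control	lncRNA	AC016746.1	5.00E-05	5.83
primary_vs_control	lncRNA	AC024940.6	5.00E-05	5.77
primary_vs_control	lncRNA	LNC01705	5.00E-05	5.72
primary_vs_control	lncRNA	AL645608.6	5.00E-05	5.68
primary_vs_control	lncRNA	HSD52	5.00E-05	-9.35
primary_vs_control	lncRNA	AL158850.2	1.00E-04	-8.35
primary_vs_control	lncRNA	MIR133A1HG	5.00E-05	-8.08
primary_vs_control	lncRNA	AC011603.3	5.00E-05	-7.92
primary_vs_control	lncRNA	AC084880.3	5.00E-05	-7.54
primary_vs_control	lncRNA	AC015878.1	5.00E-05	-7.41
primary_vs_control	lncRNA	LOC101929592	5.00E-05	-7.32
primary_vs_control	lncRNA	MLIP-AS1	5.00E-05	-7.1
primary_vs_control	lncRNA	AC117505.1	5.00E-05	-6.76
primary_vs_control	lncRNA	C10ORF71-AS1	5.00E-05	-6.63
primary_vs_control	mRNA	SPP1	0.00105	10.93
primary_vs_control	mRNA	ACP5	5.00E-05	8.93
primary_vs_control	mRNA	PCLAF	0.00065	6.91
primary_vs_control	mRNA	COL1A1	5.00E-05	6.89
primary_vs_control	mRNA	PIMREG	1.00E-04	6.81
primary_vs_control	mRNA	INSC	3.00E-04	6.78
primary_vs_control	mRNA	DGKI	0.00165	6.71
primary_vs_control	mRNA	TENM4	5.00E-05	6.57
primary_vs_control	mRNA	PTPN22	1.00E-04	6.52
primary_vs_control	mRNA	DMP1	5.00E-05	6.33
primary_vs_control	mRNA	MYBPC1	1.00E-04	-13.73
primary_vs_control	mRNA	MYH7	5.00E-05	-13.06
primary_vs_control	mRNA	MYH1	5.00E-05	-12.91
primary_vs_control	mRNA	MYH2	0.002	-12.88
primary_vs_control	mRNA	TNNT1	5.00E-05	-11.92
primary_vs_control	mRNA	TNNI2	5.00E-05	-11.28
primary_vs_control	mRNA	ANKRD2	0.0027	-10.81
primary_vs_control	mRNA	TNNC1	0.00095	-10.53
primary_vs_control	mRNA	ATP2A1	5.00E-05	-10.22
primary_vs_control	mRNA	CMYA5	5.00E-05	-10.21
metastatic_vs_primary	miRNA	hsa-miR-3653-3p	0.00139	8.36
metastatic_vs_primary	miRNA	hsa-miR-4783-3p	0.003224	7.71
metastatic_vs_primary	miRNA	hsa-miR-3144-3p	0.005005	7.1
metastatic_vs_primary	miRNA	hsa-miR-1269a	0.000269	7.01
metastatic_vs_primary	miRNA	hsa-miR-1262	0.001956	6.08
metastatic_vs_primary	miRNA	hsa-miR-4725-3p	0.001195	5.8
metastatic_vs_primary	miRNA	hsa-miR-4651	0.00269	5.66
metastatic_vs_primary	miRNA	hsa-miR-4443	0.005788	5.51
metastatic_vs_primary	miRNA	hsa-miR-760	0.003071	4.96
metastatic_vs_primary	miRNA	hsa-miR-4507	0.006545	4.89
metastatic_vs_primary	miRNA	hsa-miR-539-3p	0.000284	-9.69
metastatic_vs_primary	miRNA	hsa-miR-612	0.006778	-9.35
metastatic_vs_primary	miRNA	hsa-miR-1197	0.005934	-9.19
metastatic_vs_primary	miRNA	hsa-miR-655-3p	0.00361	-8.94
metastatic_vs_primary	miRNA	hsa-miR-889-3p	2.58E-05	-8.12
metastatic_vs_primary	miRNA	hsa-miR-381-3p	0.000726	-5.5
metastatic_vs_primary	miRNA	hsa-miR-1185-1-3p	0.000492	-5.39
metastatic_vs_primary	miRNA	hsa-miR-411-5p	0.000964	-5.3
metastatic_vs_primary	miRNA	hsa-miR-495-3p	0.000695	-5.19
metastatic_vs_primary	miRNA	hsa-miR-539-3p	0.002104	-5.13
metastatic_vs_primary	lncRNA	LINC00426	1.55E-03	5.429108
metastatic_vs_primary	lncRNA	lnc-DRD5-1	5.00E-05	4.753273
metastatic_vs_primary	lncRNA	LNC-COG5-2	6.65E-03	4.627595
metastatic_vs_primary	lncRNA	AC068254.2	5.00E-05	3.664665
metastatic_vs_primary	lncRNA	AP000997.2	1.30E-03	3.654228
metastatic_vs_primary	lncRNA	Lnc-ZNF583-5	1.10E-03	3.467332
metastatic_vs_primary	lncRNA	THRB-AS1	2.40E-03	3.304355
metastatic_vs_primary	lncRNA	C4B-AS1	4.35E-03	3.274502
metastatic_vs_primary	lncRNA	SLC9A3-AS1	5.00E-05	3.243303
metastatic_vs_primary	lncRNA	AC110285.7	3.20E-03	3.177157
metastatic_vs_primary	lncRNA	lnc-METRNL-8	5.00E-05	-6.05459
metastatic_vs_primary	lncRNA	lnc-MGMT-12	1.00E-04	-5.84527
metastatic_vs_primary	lncRNA	lnc-DUSP10-4	5.00E-05	-5.71626
metastatic_vs_primary	lncRNA	HMBOX1-IT1	1.00E-04	-4.91397
metastatic_vs_primary	lncRNA	lnc-ZNF730-6	1.55E-03	-4.7872
metastatic_vs_primary	lncRNA	WFDC21P	5.00E-05	-4.53685
metastatic_vs_primary	lncRNA	LINC02055	5.00E-05	-4.33215
metastatic_vs_primary	lncRNA	AL356417.2	1.45E-03	-4.15989
metastatic_vs_primary	lncRNA	Z98044.1	3.00E-04	-4.00363
metastatic_vs_primary	lncRNA	LOC100129940	1.15E-03	-3.995
metastatic_vs_primary	mRNA	C4B	5.00E-05	6.709397
metastatic_vs_primary	mRNA	LIPE	5.00E-05	5.931086
metastatic_vs_primary	mRNA	GAGE12C	5.00E-05	5.825597
metastatic_vs_primary	mRNA	CKMT1B	1.00E-04	5.45318
metastatic_vs_primary	mRNA	DGAT2	0.0093	5.247579
metastatic_vs_primary	mRNA	KCNK3	5.00E-05	5.206908
metastatic_vs_primary	mRNA	SOD3	5.00E-05	5.130038
metastatic_vs_primary	mRNA	ITGA7	0.00085	5.124185
metastatic_vs_primary	mRNA	RIMS2	5.00E-05	5.016506
metastatic_vs_primary	mRNA	KRT8	5.00E-04	4.979941
metastatic_vs_primary	mRNA	SPATA22	0.00525	-159.879
metastatic_vs_primary	mRNA	CTSK	5.00E-05	-7.01673
metastatic_vs_primary	mRNA	NDNF	5.00E-05	-6.31953
metastatic_vs_primary	mRNA	CHAD	0.00235	-5.52639
metastatic_vs_primary	mRNA	PRKN	0.0066	-5.26132
metastatic_vs_primary	mRNA	FNDC1	5.00E-05	-5.19914
metastatic_vs_primary	mRNA	FST	5.00E-05	-5.06677
metastatic_vs_primary	mRNA	RUFY4	5.00E-05	-4.88628
metastatic_vs_primary	mRNA	ENPP1	1.00E-04	-4.87775
metastatic_vs_primary	mRNA	DSP	2.00E-04	-4.75571
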