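id	rna_class	log2fc_a	log2fc_b	de_a	de_b
miR-223-5p	miRNA	3.2	-2.8	1	1
miR-378b	miRNA	-2.9	3.4	1	1
miR-323b-3p	miRNA	2.6	-3.1	1	1
CLSTN2	mRNA	-3.5	2.7	1	1
AC009951.1	lncRNA	-2.8	3.0	1	1
LINC01705	lncRNA	-3.1	2.5	1	1
AC090673.1	lncRNA	-2.6	2.9	1	1
ALX4	mRNA	3.3	-2.7	1	1
IGSF3	mRNA	2.8	-3.2	1	1
SULF1	mRNA	3.0	-2.6	1	1
TGFBR3	mRNA	-2.7	3.1	1	1
SPP1	mRNA	10.93	0.10	1	0
COL1A1	mRNA	6.89	-0.20	1	0
HSD52	lncRNA	-9.35	0.30	1	0
MIR133A1HG	lncRNA	-8.08	0.05	1	0
miR-612	miRNA	0.20	-9.35	0	1
miR-1262	miRNA	-0.10	6.08	0	1
miR-539-3p	miRNA	0.30	-9.69	0	1
miR-655-3p	miRNA	0.15	-8.94	0	1
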