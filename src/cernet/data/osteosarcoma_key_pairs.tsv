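mirna	target	target_class	in_contrast_a	in_contrast_b	is_key
miR-223-5p	CLSTN2	mRNA	1	1	1
miR-223-5p	AC009951.1	lncRNA	1	1	1
miR-223-5p	LINC01705	lncRNA	1	1	1
miR-223-5p	AC090673.1	lncRNA	1	1	1
miR-378b	ALX4	mRNA	1	1	1
miR-378b	IGSF3	mRNA	1	1	1
miR-378b	SULF1	mRNA	1	1	1
miR-323b-3p	TGFBR3	mRNA	1	1	1
miR-223-5p	SPP1	mRNA	1	0	0
miR-378b	COL1A1	mRNA	1	0	0
miR-323b-3p	HSD52	lncRNA	1	0	0
miR-223-5p	MIR133A1HG	lncRNA	1	0	0
miR-612	CLSTN2	mRNA	0	1	0
miR-1262	TGFBR3	mRNA	0	1	0
miR-539-3p	ALX4	mRNA	0	1	0
miR-655-3p	LINC01705	lncRNA	0	1	0
miR-223-5p	ALX4	mRNA	1	0	0
miR-378b	TGFBR3	mRNA	1	0	0
miR-323b-3p	CLSTN2	mRNA	0	1	0
miR-223-5p	SULF1	mRNA	0	1	0
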