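condition	kind	members	log2_ratios	printed_average	confirmed_suppressor
glyoxal	locus	GLO1;YML003W	2.52,3.25	2.88	GLO1
glyoxal	locus	YDR366C;YDR367W;YPR1;XRS2	3.29,2.07,2.20,2.37	2.48	YPR1
glyoxal	locus	YMR317W;ADH6	2.86,2.04	2.45	ADH6
glyoxal	locus	PBN1;LRE1	2.13,2.35	2.24
glyoxal+isonicotinamide	locus	PBN1;LRE1	4.81,4.74	4.78
glyoxal+isonicotinamide	locus	YDR366C;YDR367W;YPR1;XRS2	5.05,4.14,4.53,4.73	4.61	YPR1
glyoxal+isonicotinamide	locus	YMR317W;ADH6	4.73,4.49	4.61	ADH6
glyoxal+isonicotinamide	locus	MRPL28;STP1	3.07,4.24	3.66	STP1
glyoxal+isonicotinamide	locus	MED8;SOY1;MSI1;PGI1	4.25,4.09,3.68,2.60	3.65	MED8
glyoxal+isonicotinamide	locus	YML007C-A;YAP1;GIS4;[tS(AGA)M];TRM12;GLO1;YML003W	2.40,2.46,2.33,0.00,4.90,5.80,6.43	3.47	GLO1
glyoxal+isonicotinamide	locus	THR1;PPA1;RPN1	3.16,3.83,3.11	3.37	THR1
glyoxal+isonicotinamide	locus	ZDS2;YML108W;PML39	3.60,3.48,2.86	3.31	ZDS2
glyoxal+isonicotinamide	locus	NST1;RHO2	2.88,3.58	3.23	RHO2
glyoxal+isonicotinamide	locus	YGR125W;YGR126W	2.42,3.66	3.04	YGR126W
glyoxal+isonicotinamide	locus	FBP26;VPS35	2.95,2.96	2.96
glyoxal+isonicotinamide	locus	CCC2;[YDR271C];GLO2;DON1	2.94,0.00,4.38,4.04	2.84	GLO2
glyoxal+isonicotinamide	locus	YGL036W;MIG1	3.38,2.26	2.82
glyoxal+isonicotinamide	locus	LCP5;YER128W	2.94,2.65	2.79
glyoxal+isonicotinamide	locus	SSL1;SSK1	2.50,3.09	2.79	SSK1
glyoxal+isonicotinamide	locus	MIG2;SIP2	2.56,3.00	2.78	MIG2
glyoxal+isonicotinamide	locus	GIS3;IOC2	2.14,3.39	2.77	GIS3
glyoxal+isonicotinamide	locus	BUD22;ERG5;SOK2	2.40,2.76,2.91	2.69
glyoxal+isonicotinamide	locus	STB1;KRI1	2.91,2.40	2.66
glyoxal+isonicotinamide	locus	YKR023W;DBP7	2.73,2.45	2.59
glyoxal+isonicotinamide	locus	TRR2;CDC12	2.55,2.52	2.54
glyoxal+isonicotinamide	locus	NIP7;SRP72	2.57,2.44	2.50
glyoxal+isonicotinamide	locus	ALG12;SSK2	2.00,2.79	2.40
glyoxal+isonicotinamide	locus	RBA50;[snR84];HLR1;QCR7;APA2	3.36,0.00,3.30,3.04,2.19	2.38	HLR1
glyoxal+isonicotinamide	locus	YGR016W;YGR017W	2.42,2.18	2.30
glyoxal+isonicotinamide	locus	BSP1;YPR172W;VPS4	2.14,2.38,2.39	2.30
glyoxal+isonicotinamide	locus	DDP1;YOR164C	2.27,2.29	2.28
glyoxal+isonicotinamide	locus	CBS1;[YDL068W];COX9	2.00,0.00,2.48	1.49
glyoxal+isonicotinamide	singleton	DAM1	3.55
glyoxal+isonicotinamide	singleton	MTH1	3.10
glyoxal+isonicotinamide	singleton	CDC34	3.00
glyoxal+isonicotinamide	singleton	BUD6	2.90
glyoxal+isonicotinamide	singleton	PBS2	2.90		PBS2
glyoxal+isonicotinamide	singleton	RPI1	2.87
glyoxal+isonicotinamide	singleton	SEC6	2.85
glyoxal+isonicotinamide	singleton	YPT7	2.83
glyoxal+isonicotinamide	singleton	DNA2	2.82
glyoxal+isonicotinamide	singleton	GRE3	2.70		GRE3
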