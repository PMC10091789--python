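rsid	gene	effect_allele	other_allele	maf	inheritance_model
rs5065	NPPA	G	A	0.21	genotypic
rs198358	NPPA	C	T	0.17	genotypic
rs10494366	NOS1AP	G	T	0.36	genotypic
rs12143842	NOS1AP	T	C	0.24	genotypic
rs2740574	CYP3A4	G	A	0.04	genotypic
rs35599367	CYP3A4	A	G	0.05	genotypic
rs5443	GNB3	T	C	0.31	genotypic
rs877087	RYR3	T	C	0.46	dominant
rs2239050	CACNA1C	G	C	0.42	genotypic
rs1006737	CACNA1C	A	G	0.33	genotypic
rs1045642	ABCB1	A	G	0.45	genotypic
rs2032582	ABCB1	T	G	0.43	genotypic
rs1128503	ABCB1	A	G	0.42	genotypic
rs1048101	ADRA1A	G	A	0.40	genotypic
rs2298720	SLC14A2	C	T	0.12	genotypic
rs1042713	ADRB2	A	G	0.39	genotypic
rs1042714	ADRB2	G	C	0.43	genotypic
rs1057868	POR	T	C	0.28	genotypic
rs588076	PICALM	G	A	0.32	genotypic
rs2429427	TANC2	C	T	0.18	genotypic
rs10898815	NUMA1	A	G	0.44	genotypic
rs564991	APCDD1	C	A	0.42	genotypic
rs776746	CYP3A5	T	C	0.07	genotypic
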