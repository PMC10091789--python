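code_system	code	drug_name	drug_class
bnf	0206020A0	amlodipine	dccb_amlodipine
bnf	0206020R0	nifedipine	dccb_other
bnf	0206020C0	felodipine	dccb_other
bnf	0206020L0	lercanidipine	dccb_other
bnf	0205051R0	ramipril	ace
bnf	0205051F0	enalapril	ace
bnf	0205052N0	losartan	arb
bnf	0205052C0	candesartan	arb
bnf	0204000E0	atenolol	beta_blocker
bnf	0204000H0	bisoprolol	beta_blocker
bnf	0205040D0	doxazosin	alpha_blocker
bnf	0202010B0	bendroflumethiazide	diuretic
bnf	0202010F0	indapamide	diuretic
bnf	0205010J0	hydralazine	vasodilator
read2	bxd1.	amlodipine	dccb_amlodipine
read2	bxe1.	nifedipine	dccb_other
read2	bi31.	ramipril	ace
read2	bk21.	losartan	arb
read2	bd31.	atenolol	beta_blocker
read2	bc41.	doxazosin	alpha_blocker
read2	b211.	bendroflumethiazide	diuretic
read2	b611.	hydralazine	vasodilator
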