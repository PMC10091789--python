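vocabulary	code_prefix	outcome_label
icd10	I20	chd
icd10	I21	chd
icd10	I22	chd
icd10	I23	chd
icd10	I24	chd
icd10	I25	chd
icd10	I50	hf
icd10	N18	ckd
icd10	I60	stroke
icd10	I61	stroke
icd10	I63	stroke
icd10	I64	stroke
icd10	R60	oedema
icd9	410	chd
icd9	413	chd
icd9	428	hf
icd9	585	ckd
icd9	434	stroke
icd9	782.3	oedema
read2	G3	chd
read2	G58	hf
read2	K05	ckd
read2	G66	stroke
read2	R023	oedema
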