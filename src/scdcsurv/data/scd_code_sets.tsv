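system	code	category	wildcard
ICD9	282.41	SCD	0
ICD9	282.42	SCD	0
ICD9	282.6	SCD	0
ICD9	282.61	SCD	0
ICD9	282.62	SCD	0
ICD9	282.63	SCD	0
ICD9	282.64	SCD	0
ICD9	282.68	SCD	0
ICD9	282.69	SCD	0
ICD9	282.5	TRAIT	0
ICD10	D57	SCD	0
ICD10	D57.0	SCD	1
ICD10	D57.1	SCD	1
ICD10	D57.2	SCD	1
ICD10	D57.4	SCD	1
ICD10	D57.8	SCD	1
ICD10	D57.3	TRAIT	1
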