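pop	COP	FOR	KAR	KAS	KBOR	LET	MAR	NYK	PET	PJM
COP	0	0.00902	0.01139	0.01064	0.01060	0.01280	0.01018	0.01182	0.01176	0.01210
FOR	0.00902	0	0.01097	0.00864	0.01093	0.01112	0.01240	0.01027	0.00938	0.00992
KAR	0.01139	0.01097	0	0.01011	0.01142	0.01389	0.01291	0.01347	0.01340	0.01104
KAS	0.01064	0.00864	0.01011	0	0.01089	0.01251	0.01278	0.01230	0.01059	0.01032
KBOR	0.01060	0.01093	0.01142	0.01089	0	0.01470	0.01233	0.01365	0.01279	0.01307
LET	0.01280	0.01112	0.01389	0.01251	0.01470	0	0.01491	0.01102	0.01169	0.01234
MAR	0.01018	0.01240	0.01291	0.01278	0.01233	0.01491	0	0.01391	0.01439	0.01548
NYK	0.01182	0.01027	0.01347	0.01230	0.01365	0.01102	0.01391	0	0.01194	0.01142
PET	0.01176	0.00938	0.01340	0.01059	0.01279	0.01169	0.01439	0.01194	0	0.01193
PJM	0.01210	0.00992	0.01104	0.01032	0.01307	0.01234	0.01548	0.01142	0.01193	0
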