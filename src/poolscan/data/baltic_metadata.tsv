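code	latitude	longitude	salinity	temperature	pool_individuals
COP	55.701389	12.598611	10.76	9.85	36
FOR	60.402500	18.184722	4.73	7.82	36
KAR	56.170278	15.409444	7.55	9.43	36
KAS	62.383889	25.914444	3.15	7.51	36
KBOR	53.870556	14.284167	7.00	9.69	36
LET	59.549444	26.596944	4.63	7.80	36
MAR	56.649444	9.951389	26.82	9.88	36
NYK	58.651111	17.100556	6.58	8.20	36
PET	60.053889	29.971111	0.00	7.42	36
PJM	64.478333	24.220278	3.44	6.09	36
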