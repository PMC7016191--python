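source_system	source_code	target_system	target_code
ICD-10	E11	ICPC-2	T90
ICD-10	E10	ICPC-2	T89
ICD-10	I10	ICPC-2	K86
ICD-10	I11	ICPC-2	K87
ICD-10	I20	ICPC-2	K74
ICD-10	I21	ICPC-2	K75
ICD-10	I48	ICPC-2	K78
ICD-10	I50	ICPC-2	K77
ICD-10	I63	ICPC-2	K90
ICD-10	I70	ICPC-2	K92
ICD-10	G45	ICPC-2	K89
ICD-10	E78	ICPC-2	T93
ICD-10	E66	ICPC-2	T83/82
ICD-10	M10	ICPC-2	T92
ICD-10	H40	ICPC-2	F93
ICD-10	H25	ICPC-2	F92
ICD-10	H35	ICPC-2	F83
ICD-10	N18	ICPC-2	U99.01
ICD-10	G56	ICPC-2	N93
ICD-10	F20	ICPC-2	P72
ICD-10	J00	ICPC-2	R74
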