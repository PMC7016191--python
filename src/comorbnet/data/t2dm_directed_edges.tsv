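from	to	label	odds_ratio	direction
T90	F83	Retinopathy	23.8	directed
T90	U88	Glomerulonephritis/nephrosis	3.4	directed
T90	N94	Peripheral neuritis/neuropathy	2.7	directed
T90	D76	Pancreas ca.	2.4	directed
T90	K75	Acute myocardial infarction	2.1	directed
T90	K92	Atherosclerosis/peripheral vascular dis.	2.0	directed
T90	K87	Hypertension complicated	1.7	directed
T90	K82	Pulmonary heart dis.	1.6	directed
T90	K84	Heart dis. other	1.6	directed
T90	F93	Glaucoma	1.5	directed
T90	K91	Cerebrovascular dis.	1.4	directed
T90	T92	Gout	1.3	directed
T90	F84	Macular degeneration	1.2	directed
T83/82	T90	Obesity/overweight	2.6	directed
K74	T90	Ischaemic heart dis. with angina	1.9	directed
X77	T90	Female genital ca. other	1.4	directed
K78	T90	Atrial fibrillation/flutter	1.4	directed
P72	T90	Schizophrenia	1.3	directed
K89	T90	Transient cerebral ischaemia	1.3	directed
P71	T90	Psychosis organic, other	1.2	directed
T90	T89	Diabetes insulin dependent	3.9	undefined
T90	K86	Hypertension uncomplicated	2.8	undefined
T90	K76	Ischaemic heart dis. without angina	2.2	undefined
T90	D97	Liver dis. NOS	1.9	undefined
T90	K77	Heart failure	1.9	undefined
T90	U99.01	Chronic renal failure	1.8	undefined
T90	B82	Anaemia other, unspecified	1.7	undefined
T90	T93	Lipid disorder	1.7	undefined
T90	K90	Stroke	1.6	undefined
T90	D99	Dis. digestive system, other	1.6	undefined
T90	B81	Anaemia vitamin B12/folate deficiency	1.4	undefined
T90	F92	Cataract	1.4	undefined
T90	D98	Cholecystitis/cholelithiasis	1.3	undefined
T90	T99	Endocrine/metabolic/nutrition dis. other	1.3	undefined
T90	N93	Carpal tunnel syndrome	1.2	undefined
T90	D77	Digestive ca. other/NOS	1.2	undefined
T90	B78	Hereditary haemolytic anaemia	1.2	undefined
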