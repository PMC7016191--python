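code	label	system	chronic
T90	Diabetes non-insulin dependent	ICPC-2	1
T89	Diabetes insulin dependent	ICPC-2	1
F83	Retinopathy	ICPC-2	1
U88	Glomerulonephritis/nephrosis	ICPC-2	1
N94	Peripheral neuritis/neuropathy	ICPC-2	1
D76	Pancreas ca.	ICPC-2	1
K75	Acute myocardial infarction	ICPC-2	1
K92	Atherosclerosis/peripheral vascular dis.	ICPC-2	1
K87	Hypertension complicated	ICPC-2	1
K86	Hypertension uncomplicated	ICPC-2	1
K82	Pulmonary heart dis.	ICPC-2	1
K84	Heart dis. other	ICPC-2	1
F93	Glaucoma	ICPC-2	1
F92	Cataract	ICPC-2	1
F84	Macular degeneration	ICPC-2	1
K91	Cerebrovascular dis.	ICPC-2	1
K90	Stroke	ICPC-2	1
K89	Transient cerebral ischaemia	ICPC-2	1
T92	Gout	ICPC-2	1
T93	Lipid disorder	ICPC-2	1
T99	Endocrine/metabolic/nutrition dis. other	ICPC-2	1
T83/82	Obesity/overweight	ICPC-2	1
K74	Ischaemic heart dis. with angina	ICPC-2	1
K76	Ischaemic heart dis. without angina	ICPC-2	1
K77	Heart failure	ICPC-2	1
K78	Atrial fibrillation/flutter	ICPC-2	1
X77	Female genital ca. other	ICPC-2	1
P72	Schizophrenia	ICPC-2	1
P71	Psychosis organic, other	ICPC-2	1
D97	Liver dis. NOS	ICPC-2	1
D98	Cholecystitis/cholelithiasis	ICPC-2	1
D99	Dis. digestive system, other	ICPC-2	1
D77	Digestive ca. other/NOS	ICPC-2	1
U99.01	Chronic renal failure	ICPC-2	1
B82	Anaemia other, unspecified	ICPC-2	1
B81	Anaemia vitamin B12/folate deficiency	ICPC-2	1
B78	Hereditary haemolytic anaemia	ICPC-2	1
N93	Carpal tunnel syndrome	ICPC-2	1
R74	Upper respiratory infection acute	ICPC-2	0
D73	Gastroenteritis presumed infection	ICPC-2	0
A77	Viral disease other/NOS	ICPC-2	0
L81	Injury musculoskeletal NOS	ICPC-2	0
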