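# Published kinetic constants for WT glucokinase and 19 nonsynonymous substitutions
# (means of 3-5 preparations; s05/km in mM, kcat in 1/s, ic50 in uM).
# km_source: which ATP KM feeds the activity model (s05 = at S0.5; 50mM = fallback).
# phenotype: clinical/experimental class of the substitution.
variant	phenotype	s05_5mM_atp	n_h	s05_500uM_atp	km_atp_at_s05	km_atp_at_50mM	stability_pct	kcat	ic50_glcnac	rai_printed	rai_censor	gsirt_printed	gsirt_censor	no_activity	km_source	complete
WT	normoglycemic	8.82	1.72	5.65	0.36	0.47	86	43.8	223	1.00		5.0		0	s05	1
V33A	MODY	12.77	1.56	5.75	0.53	0.63	76	42.6	303	0.51		5.9		0	s05	1
R63S	experimental	4.44	1.64	2.75	0.23	0.35	83	57.7	487	4.17		2.9		0	s05	1
G81D	MODY									0.01	lt	7.1	ge	1		0
F150L	MODY	20.05	1.27	17.83	1.63	2.15	92	13.2	1470	0.13		6.9		0	s05	1
T209K	MODY	9.32	1.53	7.28	0.25	0.31	88	25.9	293	0.59		5.7		0	s05	1
R250C	MODY	7.94	1.57	4.84	0.37	0.45	81	36.1	287	0.94		5.0		0	s05	1
M251C	experimental	55.33	1.38					3.30		0.01	lt	7.1	ge	1		0
M251I	MODY	113.43	1.33					10.18		0.01	lt	7.1	ge	1		0
M251V	MODY	46.4	1.59	42.36	0.46	0.51	90	7.6		0.01		7.1		0	s05	1
C252R	MODY	8.37	1.61	6.52	0.27	0.34	78	11.8	290	0.27		6.2		0	s05	1
F260L	experimental	9.07	1.54	4.76	0.36	0.41	82	41.8	263	0.95		5.1		0	s05	1
G295D	MODY									0.01	lt	7.1	ge	1		0
L314P	MODY	13.63	1.40			0.30		5.9		0.11		6.9		0	50mM	0
F316V	MODY	11.20	1.66	5.92	0.47	0.69	84	45.5	250	0.51		5.7		0	s05	1
G318R	MODY	8.53	1.63	4.67	0.37	0.53	84	34.0	293	0.67		5.3		0	s05	1
G385W	MODY							0.14		0.01	lt	7.1	ge	1		0
F419L	MODY	15.00	1.67	9.57	0.33	0.43	84	25.4	277	0.19		6.6		0	s05	1
C434Y	MODY	7.36	1.66	4.50	0.37	0.45	95	29.0	217	0.71		5.1		0	s05	1
A454E	MODY	24.49	1.39	14.06	1.49	1.36	90	6.7	513	0.04		7.0		0	s05	1
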