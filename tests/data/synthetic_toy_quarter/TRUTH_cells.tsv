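drug_group	pt	theta	e_a	e_b	e_c	e_d	obs_a	obs_b	obs_c	obs_d
CDOX	Anaemia	1	2.250	7.750	42.750	147.250	1	15	40	144
CDOX	Cardiotoxicity	1	2.808	9.671	42.192	145.329	1	12	40	147
CDOX	Febrile neutropenia	8	13.333	8.981	31.667	146.019	13	9	28	150
CDOX	Malignant neoplasm progression	1	2.250	7.750	42.750	147.250	1	8	40	151
CDOX	Nausea	1	2.250	7.750	42.750	147.250	2	5	39	154
CDOX	Neutropenia	1	2.250	7.750	42.750	147.250	2	6	39	153
CDOX	Palmar-plantar erythrodysaesthesia syndrome	1	3.913	13.476	41.087	141.524	2	16	39	143
CDOX	Pneumonia	1	2.250	7.750	42.750	147.250	4	7	37	152
CDOX	Pyrexia	1	2.250	7.750	42.750	147.250	2	9	39	150
CDOX	Sepsis	1	2.250	7.750	42.750	147.250	3	10	38	149
DOXIL	Anaemia	1	1.350	8.650	25.650	164.350	1	15	37	147
DOXIL	Cardiotoxicity	1	1.685	10.794	25.315	162.206	2	11	36	151
DOXIL	Febrile neutropenia	1	3.013	19.302	23.988	153.698	3	19	35	143
DOXIL	Malignant neoplasm progression	1	1.350	8.650	25.650	164.350	1	8	37	154
DOXIL	Nausea	1	1.350	8.650	25.650	164.350	2	5	36	157
DOXIL	Neutropenia	1	1.350	8.650	25.650	164.350	2	6	36	156
DOXIL	Palmar-plantar erythrodysaesthesia syndrome	8	8.000	9.389	19.000	163.611	14	4	24	158
DOXIL	Pneumonia	1	1.350	8.650	25.650	164.350	1	10	37	152
DOXIL	Pyrexia	1	1.350	8.650	25.650	164.350	2	9	36	153
DOXIL	Sepsis	1	1.350	8.650	25.650	164.350	6	7	32	155
MYOCET	Anaemia	1	0.900	9.100	17.100	172.900	0	16	13	171
MYOCET	Cardiotoxicity	4	3.130	9.348	14.870	172.652	3	10	10	177
MYOCET	Febrile neutropenia	1	2.008	20.306	15.992	161.694	3	19	10	168
MYOCET	Malignant neoplasm progression	1	0.900	9.100	17.100	172.900	0	9	13	178
MYOCET	Nausea	1	0.900	9.100	17.100	172.900	0	7	13	180
MYOCET	Neutropenia	1	0.900	9.100	17.100	172.900	2	6	11	181
MYOCET	Palmar-plantar erythrodysaesthesia syndrome	1	1.565	15.824	16.435	166.176	1	17	12	170
MYOCET	Pneumonia	1	0.900	9.100	17.100	172.900	2	9	11	178
MYOCET	Pyrexia	1	0.900	9.100	17.100	172.900	1	10	12	177
MYOCET	Sepsis	1	0.900	9.100	17.100	172.900	0	13	13	174
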