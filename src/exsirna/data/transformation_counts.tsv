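plasmid	construct	strain	genotype	albino	bright_yellow
pMAT647	s-transgene	wild-type	wt	34	66
pMAT647	s-transgene	MU413	ago1	0	300
pMAT1253	hpRNA	wild-type	wt	104	33
pMAT1253	hpRNA	MU413	ago1	0	358
pMAT1337	hpRNA/ago-1+	wild-type	wt	189	10
pMAT1337	hpRNA/ago-1+	MU413	ago1	187	13
pLEU4	control	wild-type	wt	0	102
pLEU4	control	MU413	ago1	0	126
pMAT647	s-transgene	wild-type	wt	92	108
pMAT647	s-transgene	MU416	ago2	95	99
pMAT647	s-transgene	MU417	ago2	122	108
pMAT647	s-transgene	MU414	ago3	81	118
pMAT647	s-transgene	MU415	ago3	74	122
pMAT1253	hpRNA	wild-type	wt	306	38
pMAT1253	hpRNA	MU416	ago2	219	11
pMAT1253	hpRNA	MU417	ago2	172	17
pMAT1253	hpRNA	MU414	ago3	186	14
pMAT1253	hpRNA	MU415	ago3	190	10
pLEU4	control	wild-type	wt	0	127
pLEU4	control	MU416	ago2	0	27
pLEU4	control	MU417	ago2	0	28
pLEU4	control	MU414	ago3	0	25
pLEU4	control	MU415	ago3	0	28
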