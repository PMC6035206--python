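patient	age_years	diagnosis	figo_stage	delay_months	sample_age_years
1	54.8	HGSC	IV	1.4	5.1
2	70.5	HGSC	IA	1.6	7.2
3	54.7	HGSC	IV	-54.8	18.6
4	66.7	HGSC	IV	-16.3	12.4
5	50.2	HGSC	IIIC	5.1	14.1
6	72	HGSC	IV	2.5	12.2
7	62.8	HGSC	IIIC	2.6	13.5
8	80	HGSC	IIIC	-28.4	16.2
9	81.4	CCC	IA	-72.4	11.6
10	55.2	CS	IIIC	-3.5	4.4
11	62.3	HGSC	IIIC	1.6	9.6
12	51.2	HGSC	IIIA	6	1.4
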