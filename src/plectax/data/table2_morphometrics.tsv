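group	nid	stage	label	tail_length	anal_body_width	c_prime_printed	amphid_width	neck_width	amphid_ratio_printed
3	N12485	F	Short	65	26.7	2.4	2	19	0.11
3	N13239	J	Short	35	15	2.3	2.5	17.5	0.14
3	N13543	J	Short	62	28	2.2	NA	NA	NA
3	N13030	J	Short	70	29.4	2.4	2.5	NA	NA
3	N13045	J	Short	61	28.9	2.1	2.5	16.6	0.15
3	N13255	J	Short	65	27.5	2.4	NA	NA	NA
3	N13357	J	Short	66	28.9	2.3	2	17.5	0.11
3	N13530	J	Short	63	25.2	2.5	2	16.2	0.12
3	N13538	J	Short	63	28.9	2.2	2	17	0.12
3	N11764	J	Short	70	29	2.4	2.5	12	0.21
3	N11765	J	Short	74	34	2.2	2	12	0.17
4	N13280	J	Short	77	25	3.1	2.5	17	0.15
4	N13608	F	Short	94	33.6	2.8	2	20.4	0.10
6	N13176	J	Short	72	27.6	2.6	3	15.7	0.19
6	N13287	J	Short	75	27.2	2.8	2.5	17	0.15
6	N13425	J	Short	92	33.6	2.7	3	18.3	0.16
17	N13180	F	Long	129	33.2	3.9	4	17.9	0.22
17	N13460	F	Long	120	28.5	4.2	5	20.4	0.25
18	N13465	F	Long	91.6	17.4	5.3	3.5	13.6	0.26
19	N12733	F	Long	105	18	5.8	3.3	12.5	0.26
20	N13403	F	Long	92.5	17	5.4	3.5	14	0.25
20	N13479	F	Long	94	18.3	5.1	3.5	15.3	0.23
20	N13486	F	Long	85	18.3	4.6	4	14.5	0.28
20	N13444	F	Long	88	16.2	5.4	4	14.9	0.27
20	N13440	J	Long	102	20	5.1	4	15.3	0.26
20	N13118	F	Long	94	18.7	5.0	3	14.9	0.20
20	N13133	J	Long	110	20.8	5.3	4.5	16.2	0.28
20	N13203	F	Long	97	19.6	4.9	3.5	14.9	0.23
20	N13225	F	Long	98	17	5.8	4.5	14.9	0.30
20	N13329	F	Long	96	20.4	4.7	4	14.9	0.27
20	N13344	J	Long	78	13.6	5.7	3.5	11.5	0.30
20	N13369	F	Long	100	17	5.9	4	14.5	0.28
20	N13471	F	Long	94	17.9	5.2	4	13.6	0.29
20	N13491	F	Long	99	19.6	5.0	NA	NA	NA
20	N13587	F	Long	93	19.1	4.9	3.5	15.7	0.22
20	N13598	F	Long	78	17.9	4.4	4	13.6	0.29
20	N13601	F	Long	91	18.3	5.0	3.5	14	0.25
20	N13622	F	Long	88	16.2	5.4	4.5	14	0.32
20	N13628	F	Long	108	20	5.4	3.5	14.9	0.23
20	N13641	F	Long	92	18.3	5.0	3.4	14.9	0.23
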