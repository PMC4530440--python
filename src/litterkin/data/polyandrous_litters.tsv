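species	litter	tl_mm	n_embryos	n_sires	skew	rel_prob
A	Mm152	1630	10	2	8:2	1.54e-6
A	Mm159	1350	6	2	3:3	5.76e-8
A	Mm203	1550	16	2	3:12	1.02e-10
A	Mm229	1585	18	2	17:1	4.14e-10
A	Mm237	1310	15	2	14:1	3.80e-6
A	Mm240	1400	9	2	4:5	3.54e-5
A	Mm266	1420	15	2	4:10	3.63e-9
A	Mm274	1375	12	2	3:4	3.61e-3
A	Mm275	1320	9	3	4:3:2	1.84e-5
B	Mp154	1255	27	2	13:14	1.9e-11
B	Mp287	1250	14	2	5:9	2.38e-10
B	Mp1_6.9	1170	16	2	14:2	4.09e-10
B	Mp4_6.9	1180	15	2	6:9	7.85e-10
B	Mp6_6.9	1320	30	2	28:2	1.42e-9
B	Mp7_6.9	1410	29	2	14:15	7.8e-10
B	Mp9_6.9	1290	26	2	18:5	NA
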