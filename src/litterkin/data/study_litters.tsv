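species	mother	tl_mm	n_embryos	site	date
A	Mm152	1630	10	Mazara del Vallo	12.2013
A	Mm155	1270	4	Mazara del Vallo	12.2013
A	Mm156	1410	4	Mazara del Vallo	12.2013
A	Mm159	1350	6	Mazara del Vallo	12.2013
A	Mm161	1210	3	Mazara del Vallo	12.2013
A	Mm203	1550	16	Chioggia	11.09.2012
A	Mm229	1585	18	Mazara del Vallo	17.09.2012
A	Mm230	1490	15	Mazara del Vallo	17.09.2012
A	Mm235	1420	7	Chioggia	26.09.2012
A	Mm237	1310	15	Chioggia	26.09.2012
A	Mm240	1400	9	Chioggia	26.09.2012
A	Mm247	1460	16	Chioggia	02.10.2012
A	Mm266	1420	15	Chioggia	03.10.2012
A	Mm274	1375	12	Chioggia	03.10.2012
A	Mm275	1320	9	Chioggia	03.10.2012
A	Mm278	1520	18	Chioggia	03.10.2012
A	Mm279	1480	15	Chioggia	03.10.2012
A	Mm280	1310	6	Chioggia	03.10.2012
A	Mm288	1260	6	Mazara del Vallo	17.09.2012
B	Mp154	1255	27	Mazara del Vallo	12.2013
B	Mp183	1250	34	Chioggia	29.08.2012
B	Mp184	1290	35	Chioggia	29.08.2012
B	Mp287	1250	14	Ancona	21.10.2008
B	Mp3_14.7	1290	10	Chioggia	14.07.2011
B	Mp4_14.7	1410	27	Chioggia	14.07.2011
B	Mp7_14.7	1290	31	Chioggia	14.07.2011
B	Mp1_6.9	1170	16	Chioggia	06.09.2011
B	Mp4_6.9	1180	15	Chioggia	06.09.2011
B	Mp6_6.9	1320	30	Chioggia	06.09.2011
B	Mp7_6.9	1410	29	Chioggia	06.09.2011
B	Mp9_6.9	1290	26	Chioggia	06.09.2011
B	Mp1_21.9	1100	9	Chioggia	21.09.2011
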