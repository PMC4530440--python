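locus	species_A_alleles	species_B_alleles	status
Gg4	198	199	fixed
Gg20	280	281;282	non_overlapping
MaTJ5	159	157	fixed
Mca33	194;200	197	non_overlapping
McaB26	224;229	224	overlapping
Mh1	203	201;205	non_overlapping
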