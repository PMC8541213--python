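purpose	name	sequence	specific_positions	padded_5prime_count
BAW	BAW_5F3	GGAGCTATATGACCCCCTGTC	18,19,20	0
BAW	BAW_5B3	TCCTGTTGCTATAAAGAATGTAGAC	24	0
BAW	BAW_5FIP	GCTCAAGTAACTGATACTCCTGATCTAATTTAATCCATTTCAAATTCCTCT		0
BAW	BAW_5BIP	ATTCCCAAATAACTCAAGGACTATTCTTCAAAATATTCATATGCTTGT		0
BAW	BAW_5LF	CTGATCTAATTAAAATAATAGTATTAAG		0
BAW	BAW_5LB	TTACAATTATTTTAGGAATTTATTTTAC		0
FAW	FAW_1F3	TTCTAGTAGGATATTTAATATCAAGCT	25,26	0
FAW	FAW_1B3	CGAAAATTATTACTTGATATATCATTTGTA	28,29	0
FAW	FAW_1FIP	CTGGTAAAATAGTTCAAATTAATAATATATTAATCGATTTTTATTAGAAGGTC		0
FAW	FAW_1BIP	CCTTCACTACGATTATTATATTTATTAGAACTTCAATATCATTGATGACCA		0
FAW	FAW_1LF	GTAAAATAGTTCAAATTAATTCAATTATTT		0
FAW	FAW_1LB	CTTAATAATCCTTTAATTACATTAAAATC		0
TCW	TCW_3F3	GTTTCTTTACCTTTATGATTAAGTTTC	26
TCW	TCW_3B3	ATAATCTACTAAATGGAAAGGATGG	24	0
TCW	TCW_3FIP	GGTATTAAAATAGTGGGTGTTCCTTGATTAAATAACTCTCAACATATATTCATTCA		0
TCW	TCW_3BIP	TTGAAACTATTAGAAATATTATTCGACCGACCTGCAATCATATTAGCTGTT		0
TCW	TCW_3LF	GGGTGTTCCTTGAGGAATTATA		0
TCW	TCW_3LB	GGGAACATTAGCAGTTCGATT		0
ACL	ACL_2F3	CCTTACCATTATGATTAAGCTTTATG	19,22,25	0
ACL	ACL_2B3	GACTATTCCTCTAACTAAAACTATTGT	25,26	0
ACL	ACL_2FIP	AGTTATTAATAAATGACCTGCGATTATATTAATATTATTCGACCAGGAACAT		0
ACL	ACL_2BIP	CTGGACCTTCTATACCAAATTATTTTATATAACCGCAACTGCTGAT		0
ACL	ACL_2LF	AGCTGTTAATCGAACTGCTA		0
ACL	ACL_2LB	TAATTCAAATTTTATTATTAATCTTAGA		0
PCR	LCO1490	GGTCAACAAATCATAAAGATATTGG		0
PCR	HCO2198	TAAACTTCAGGCTGACCAAAAAATCA		0
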