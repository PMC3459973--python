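rsid	group	sequence	tag
rs12722495	group 1	CCTTCCAGTTCCTTGAATACTTCCAA[A/G]TCGCACTTAGGATTGAAACTCACCA	1
rs41295061	group 1	TCTGAAGAACCCAGAAGCGACATTAG[A/C]AAGGGGTTCGTTTCACGGAATCCAA	0
rs12722522	group 1	TCGAAGAAAGAGGGCTCATAATTCCA[C/T]GTCAGGGAAGAGCCGCTGGCCTGCC	0
rs12722508	group 1	TGTTGAAAAGAATAGAACCCACCCAC[A/T]GAAACTATCAGAGATCAAATGTTGT	0
rs41295049	group 1	GTGGTGGTATAACATGCAAATGAGAG[A/G]TGCCCAGGGCAAGAAAACTTGCTCT	0
rs41295065	group 1	AGTGGGAGGAAAAGAGAAGAATCAAC[A/G]TGACTCAGATTTCTGGCTTGCGTAC	0
rs7909519	group 1	AGTATAATAGTCAATATAATTAAAAT[G/T]ATTACTTATGCAGTAATTAATTATG	0
rs41295063	group 1	CACCCAGGCTGGAGTGCAACAGTGCA[A/G]TCTCAGCTCACTGCAACTTCTGCCT	0
rs11594656	group 2	CCAAGGCGGTTCCTTGGTCTGTAGAG[A/T]GAAGGCATCATAGTGAGAAAAGCCA	1
rs11597367	group 2	TACTGGGATTACAAGTGTGAGCCACC[A/G]CACCCAGCGGTTGTGGGCACTCTGA	0
rs35285258	group 2	TTTCTTCTTTTTTAACTTCTATCCCA[C/T]TCATTATACCAAGATCAAACAATAA	0
rs2104286	group 3	TAGATATAGTCATGGTAACACAAGTC[A/G]TATGTGGTAAGATCTACTGAGCATG	1
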