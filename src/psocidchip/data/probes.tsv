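code	role	target_species	sequence	linker	label	length	start	end
Lbr	species	Liposcelis brunnea	AGGATCGAAGAAGGTCTTCCTCTC	NH2-(T)15	.	24	394	417
Len	species	Liposcelis entomophila	GAAGTAAGTCGATTTCCGAAACGTA	NH2-(T)15	.	25	123	147
Lde	species	Liposcelis decolor	GATAACAAGCATGCCCTAAGCAC	NH2-(T)15	.	23	256	278
Lpe	species	Liposcelis pearmani	TTCCTCGTCACGTTAGTCAGTTTG	NH2-(T)15	.	24	304	327
Lru	species	Liposcelis rufa	GGAAGAAGAACACTATAGAGAACGAT	NH2-(T)15	.	26	186	211
Lme	species	Liposcelis mendax	CTTCGGCACGAATAATGTGGAG	NH2-(T)15	.	22	106	127
Lbo	species	Liposcelis bostrychophila	CTGTGGAAGTGTCGAAAGATTTGAG	NH2-(T)15	.	25	118	142
Lco	species	Liposcelis corrodens	TGCAAAAACGGTTTCTCTGCGT	NH2-(T)15	.	22	240	261
Lpa	species	Liposcelis paeta	GTTTACCGACGATTTTGAGAGTGTC	NH2-(T)15	.	25	98	122
Ltr	species	Liposcelis tricolor	GAAAGAGAATGTCTCAGTAAATGGT	NH2-(T)15	.	25	184	208
A	anchor	.	GTCTTGTCTGATCTGAG	NH2-3prime	Cy5	17	.	.
P	positive	.	GGTGACGGGGAATCAGGGTTCGATT	NH2-(T)15	.	25	.	.
N	negative	.	GACTATAGTATAAGCGCGGTCCA	NH2-(T)15	.	23	.	.
B	blank	.	.	.	.	0	.	.
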