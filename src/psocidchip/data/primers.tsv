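name	sequence	label	direction	molar_ratio_weight
FOR1	TGTGAACTGCAGGACACATG	.	forward	1
REV1	GTCTTGTCTGATCTGAG	.	reverse	1
Cy5-REV1	GTCTTGTCTGATCTGAG	Cy5	reverse	20
FOR2	TGTGAACTGCAGGACACATGCAACTTTCGATGGTAGTCGCCG	.	forward	1
REV2	GTCTTGTCTGATCTGAGGCCTGCTGCCTTCCTTGGATG	.	reverse	1
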