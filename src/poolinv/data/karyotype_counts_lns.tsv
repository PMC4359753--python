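population	n	In(2L)t	In(2R)Ns	In(3L)P	In(3R)P	In(3R)Mo	In(3R)C
Base	37	12	2	1	4	4	5
Cold - R1	36	13	0	3	3	7	2
Cold - R2	45	4	0	2	0	12	12
Cold - R3	30	10	2	0	0	6	3
Hot - R1	42	15	0	2	0	2	19
Hot - R2	44	10	0	3	2	1	15
Hot - R3	41	16	0	0	0	1	17
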