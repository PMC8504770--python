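round	code	order	consensus_count	percent	bp
all	RLX	LTR	45	1.26	1932824
all	RIX	LINE	28	0.37	568834
all	RSX	SINE	3	0.04	65866
all	RPX	Penelope	5	0.05	72120
all	RXX	TRIM	3	0.01	13707
all	DTX	TIR	90	1.13	1727136
all	MITE	MITE	83	0.89	1360651
all	DHX	Helitron	7	0.08	120684
all	DMX	Maverick	11	0.15	228938
all	DXX	Unknown	1	0.01	19151
all	PHG	-	44	0.98	1507976
all	noCat	-	843	11.85	18148362
all	SSR	-	5	0.02	31970
flc	RLX	LTR	38	1.17	1789590
flc	RIX	LINE	28	0.39	590859
flc	RSX	SINE	3	0.03	52834
flc	RPX	Penelope	2	0.02	26689
flc	RXX	TRIM	2	0.01	12372
flc	DTX	TIR	79	1.03	1575291
flc	MITE	MITE	84	0.87	1338036
flc	DHX	Helitron	7	0.08	121020
flc	DMX	Maverick	10	0.15	228968
flc	DXX	Unknown	1	0.01	19148
flc	PHG	-	43	0.981	1502303
flc	noCat	-	738	11.6	17775484
flc	SSR	-	3	0.02	32341
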