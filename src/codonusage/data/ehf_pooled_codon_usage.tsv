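amino_acid	codon	count	rscu
Phe	UUU	87	0.64
Phe	UUC	164	1.36
Leu	UUA	71	0.70
Leu	UUG	74	0.73
Leu	CUU	66	0.61
Leu	CUC	187	1.74
Leu	CUA	33	0.32
Leu	CUG	201	1.91
Ile	AUU	85	0.89
Ile	AUC	197	2.07
Ile	AUA	3	0.03
Val	GUU	23	0.36
Val	GUC	56	1.08
Val	GUA	67	1.27
Val	GUG	69	1.29
Ser	UCU	32	0.36
Ser	UCC	109	1.24
Ser	UCA	35	0.41
Ser	UCG	10	0.12
Ser	AGU	81	0.91
Ser	AGC	259	2.95
Pro	CCU	95	1.35
Pro	CCC	66	0.96
Pro	CCA	64	1.00
Pro	CCG	45	0.69
Thr	ACU	74	0.66
Thr	ACC	211	1.90
Thr	ACA	110	1.00
Thr	ACG	51	0.44
Ala	GCU	37	0.54
Ala	GCC	116	1.76
Ala	GCA	63	0.97
Ala	GCG	49	0.72
Tyr	UAU	110	0.83
Tyr	UAC	156	1.17
His	CAU	81	0.63
His	CAC	165	1.37
Gln	CAA	67	0.35
Gln	CAG	327	1.65
Asn	AAU	189	0.85
Asn	AAC	253	1.15
Lys	AAA	242	1.06
Lys	AAG	214	0.94
Asp	GAU	73	0.46
Asp	GAC	243	1.54
Glu	GAA	276	1.24
Glu	GAG	168	0.76
Cys	UGU	3	0.04
Cys	UGC	107	1.96
Arg	CGU	34	0.62
Arg	CGC	33	0.59
Arg	CGA	61	1.10
Arg	CGG	68	1.36
Arg	AGA	77	1.47
Arg	AGG	48	0.88
Gly	GGU	70	0.70
Gly	GGC	101	0.99
Gly	GGA	95	0.94
Gly	GGG	137	1.38
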