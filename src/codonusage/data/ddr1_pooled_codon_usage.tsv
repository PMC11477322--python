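amino_acid	codon	count	rscu
Phe	UUU	318	0.77
Phe	UUC	506	1.23
Leu	UUA	105	0.24
Leu	UUG	155	0.36
Leu	CUU	182	0.42
Leu	CUC	664	1.52
Leu	CUA	141	0.33
Leu	CUG	1368	3.14
Ile	AUU	74	0.36
Ile	AUC	522	2.52
Ile	AUA	26	0.13
Val	GUU	118	0.32
Val	GUC	301	0.83
Val	GUA	75	0.21
Val	GUG	958	2.63
Ser	UCU	157	0.75
Ser	UCC	289	1.38
Ser	UCA	77	0.37
Ser	UCG	79	0.38
Ser	AGU	148	0.71
Ser	AGC	505	2.41
Pro	CCU	423	0.89
Pro	CCC	864	1.82
Pro	CCA	343	0.72
Pro	CCG	268	0.56
Thr	ACU	124	0.60
Thr	ACC	443	2.15
Thr	ACA	126	0.61
Thr	ACG	133	0.65
Ala	GCU	253	0.60
Ala	GCC	1005	2.38
Ala	GCA	177	0.42
Ala	GCG	252	0.60
Tyr	UAU	281	0.87
Tyr	UAC	366	1.13
His	CAU	150	0.58
His	CAC	369	1.42
Gln	CAA	74	0.19
Gln	CAG	682	1.81
Asn	AAU	212	0.66
Asn	AAC	427	1.34
Lys	AAA	45	0.16
Lys	AAG	513	1.84
Asp	GAU	475	0.79
Asp	GAC	726	1.21
Glu	GAA	150	0.25
Glu	GAG	1049	1.75
Cys	UGU	127	0.62
Cys	UGC	282	1.38
Arg	CGU	95	0.35
Arg	CGC	428	1.59
Arg	CGA	127	0.47
Arg	CGG	630	2.33
Arg	AGA	62	0.23
Arg	AGG	277	1.03
Gly	GGU	151	0.30
Gly	GGC	825	1.64
Gly	GGA	268	0.53
Gly	GGG	767	1.53
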