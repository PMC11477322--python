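species	T3s	C3s	A3s	G3s	CAI	CBI	Fop	Nc	GC3s	GC	Gravy	Aromo
Bos taurus	17.23	47.39	11.21	44.48	0.197	0.071	0.442	41.49	75.90	63.30	-0.23	0.09
Bos indicus x Bos taurus	17.49	46.58	11.30	45.61	0.199	0.066	0.441	41.59	75.70	62.90	-0.22	0.09
Bos javanicus	17.23	47.39	11.21	44.48	0.198	0.072	0.443	41.67	75.90	63.30	-0.22	0.09
Bos indicus	16.73	47.94	11.22	44.39	0.198	0.082	0.448	41.72	76.30	63.40	-0.20	0.09
Bos mutus	17.04	47.72	11.02	44.43	0.199	0.082	0.449	41.78	76.20	63.30	-0.20	0.09
Bubalus carabanensis	16.82	47.85	11.27	44.44	0.202	0.083	0.449	41.80	76.20	63.40	-0.22	0.09
Bubalus bubalis	17.08	47.13	11.23	45.81	0.205	0.081	0.450	41.82	76.10	63.00	-0.21	0.09
Capra hircus	17.21	47.40	10.41	46.00	0.207	0.087	0.453	41.85	76.60	63.30	-0.22	0.09
Ovis aries	17.98	46.59	10.59	45.80	0.208	0.088	0.454	41.94	75.80	63.00	-0.21	0.09
Cervus elaphus	18.77	46.28	11.11	44.23	0.204	0.083	0.450	41.96	74.60	62.90	-0.22	0.09
Dama dama	18.41	46.87	11.24	43.86	0.205	0.087	0.452	42.00	74.90	63.00	-0.22	0.09
Moschus berezovskii	18.12	46.68	10.92	44.48	0.203	0.074	0.444	42.00	75.30	63.20	-0.21	0.09
Cervus canadensis	18.90	46.15	10.82	44.53	0.204	0.083	0.450	42.01	74.70	63.00	-0.22	0.09
Globicephala melas	18.35	47.23	10.12	45.13	0.210	0.094	0.456	42.02	75.90	63.20	-0.27	0.09
Phocoena sinus	18.28	46.74	10.53	45.13	0.214	0.101	0.460	42.02	75.60	63.20	-0.22	0.09
Mesoplodon densirostris	18.54	46.08	11.37	44.76	0.208	0.083	0.449	42.14	74.70	62.90	-0.22	0.09
Lagenorhynchus albirostris	18.12	46.68	10.66	45.21	0.210	0.097	0.457	42.16	75.60	63.10	-0.22	0.09
Delphinus delphis	18.38	46.41	10.66	45.21	0.210	0.091	0.454	42.19	75.40	63.00	-0.22	0.09
Tursiops truncatus	18.12	46.81	10.66	45.06	0.211	0.095	0.456	42.19	75.60	63.10	-0.22	0.09
Neophocaena asiaeorientalis	18.54	46.48	10.53	45.13	0.214	0.101	0.460	42.21	75.30	63.10	-0.22	0.09
Balaenoptera ricei	19.35	45.75	10.56	45.05	0.206	0.076	0.445	42.32	74.60	62.80	-0.23	0.09
Monodon monoceros	18.64	46.28	11.24	44.46	0.211	0.096	0.456	42.52	74.70	62.80	-0.22	0.09
Orcinus orca	18.38	46.28	10.81	45.21	0.209	0.090	0.452	42.57	75.30	63.00	-0.22	0.09
Physeter catodon	19.17	45.63	10.55	45.28	0.208	0.089	0.452	42.66	74.80	63.00	-0.22	0.09
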