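species	T3s	C3s	A3s	G3s	CAI	CBI	Fop	Nc	GC3s	GC	Gravy	Aromo
Bos taurus	21.38	46.54	30.92	32.87	0.277	0.215	0.554	57.52	59.90	49.10	-0.95	0.10
Bos indicus x Bos taurus	22.67	49.78	25.73	34.02	0.292	0.226	0.560	54.01	63.10	50.70	-0.81	0.11
Bos javanicus	21.38	46.54	30.92	32.87	0.277	0.215	0.554	57.52	59.90	49.10	-0.95	0.10
Bos indicus	27.37	47.37	21.71	33.54	0.304	0.187	0.536	50.46	61.70	50.80	-0.47	0.10
Bos mutus	21.95	49.76	28.04	33.52	0.287	0.206	0.550	53.46	62.30	50.40	-0.87	0.12
Bubalus carabanensis	25.57	47.03	25.00	33.16	0.276	0.199	0.542	54.68	60.90	50.00	-0.64	0.12
Bubalus bubalis	24.22	48.88	26.34	33.16	0.290	0.204	0.548	54.06	61.60	50.10	-0.79	0.11
Capra hircus	23.21	48.66	27.80	32.81	0.284	0.218	0.555	55.03	61.20	50.20	-0.80	0.11
Ovis aries	34.60	37.26	23.67	31.90	0.249	0.108	0.483	54.81	53.60	49.40	-0.28	0.12
Cervus elaphus	23.21	49.11	25.73	34.02	0.274	0.187	0.537	53.93	62.60	50.80	-0.79	0.11
Dama dama	22.64	50.00	24.74	33.71	0.284	0.242	0.567	53.56	63.60	51.00	-0.68	0.12
Moschus berezovskii	21.88	50.00	25.73	34.72	0.288	0.230	0.562	53.42	63.70	51.20	-0.78	0.11
Cervus canadensis	23.21	49.11	25.24	34.54	0.274	0.187	0.537	54.31	63.00	50.90	-0.79	0.11
Globicephala melas	21.17	50.45	26.79	33.67	0.272	0.198	0.544	52.53	63.30	50.90	-0.77	0.11
Phocoena sinus	21.17	49.55	28.23	33.33	0.269	0.185	0.537	53.24	62.30	50.60	-0.76	0.11
Mesoplodon densirostris	22.97	49.55	26.96	33.51	0.272	0.175	0.532	52.32	62.10	50.20	-0.80	0.12
Lagenorhynchus albirostris	19.23	48.08	32.03	32.64	0.251	0.175	0.532	56.16	60.70	49.10	-0.92	0.10
Delphinus delphis	21.72	50.23	26.44	33.85	0.271	0.202	0.546	53.08	63.20	50.70	-0.78	0.11
Tursiops truncatus	19.87	46.79	32.68	32.64	0.253	0.175	0.532	57.44	59.70	48.80	-0.92	0.10
Neophocaena asiaeorientalis	21.17	49.55	28.23	33.33	0.269	0.185	0.537	53.24	62.30	50.60	-0.76	0.11
Balaenoptera ricei	20.27	51.35	27.05	34.02	0.266	0.198	0.544	53.15	64.10	50.80	-0.80	0.11
Monodon monoceros	20.72	50.90	27.40	33.51	0.272	0.199	0.544	53.05	63.30	50.70	-0.76	0.11
Orcinus orca	19.23	47.44	32.68	32.64	0.253	0.175	0.532	56.58	60.20	49.00	-0.92	0.10
Physeter catodon	21.62	50.45	27.05	33.51	0.270	0.198	0.544	52.62	63.00	50.60	-0.79	0.11
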