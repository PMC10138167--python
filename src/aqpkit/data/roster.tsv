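# Sweet cherry (P. avium 'Mazzard F12/1') aquaporin roster: 28 members with
# subfamily, length, NPA I/II triplets, ar/R selectivity filter, Froger P1-P5,
# ProtParam-style Mw (kDa) / Ip, Ka/Ks, GRAVY, HMM transmembrane-domain count
# (tdp; lookup only) and predicted subcellular localization (lookup only).
# Transcription note: the row printed "PruavNIP4:2" is normalized to
# "PruavNIP4;2" (colon -> semicolon).
name	subfamily	aa_length	npa1	npa2	arR	froger	mw	ip	kaks	gravy	tdp	localization_wp	localization_pp
PruavNIP1;1	NIP	281	NPA	NPA	WVAR	FSAYI	29.77	9.30	0.6	0.432	6	Plas	CM
PruavNIP2;1	NIP	291	NPA	NPA	GSGR	LTAYV	30.91	8.64	0.63	0.287	6	Plas	CM
PruavNIP4;1	NIP	267	NPA	NPA	WVAR	LSAYF	28.18	6.41	0.17	0.722	6	Plas	CM
PruavNIP4;2	NIP	248	NPA	NPA	WVAR	LSAYI	26.06	6.40	0.19	0.732	6	Plas	CM
PruavNIP5;1	NIP	298	NPS	NPI	SIGR	FTAYI	31.26	7.64	0.11	0.517	6	Plas	CM
PruavNIP5;2	NIP	280	NPS	NPV	A-GR	FTAYL	29.28	8.85	0.58	0.298	5	Vacu	CM
PruavNIP6;1	NIP	307	NPS	NPV	TIAR	FTAYL	31.89	8.34	0.14	0.415	6	Plas	CM
PruavNIP7;1	NIP	300	NPA	NPA	AVGR	YSAYI	31.99	5.82	0.23	0.535	6	Plas	CM
PruavPIP1;1	PIP	286	NPA	NPA	FHTR	ESAFW	30.79	9.28	0.45	0.282	5	Plas	CM
PruavPIP1;2	PIP	290	NPA	NPA	FIGR	QSAFW	30.85	9.20	0.36	0.379	6	Plas	CM
PruavPIP1;3	PIP	286	NPA	NPA	FHTR	QSAFW	30.66	9.25	0.31	0.331	6	Plas	CM
PruavPIP2;1	PIP	287	NPA	NPA	FHTR	QSAFW	30.52	8.94	0.25	0.511	6	Plas	CM
PruavPIP2;2	PIP	281	NPA	NPA	FHTR	QSAFW	30.04	7.00	0.38	0.420	6	Plas	CM
PruavPIP2;3	PIP	284	NPA	NPA	FHTR	QSAFW	30.07	6.89	0.29	0.505	6	Plas	CM
PruavPIP2;4	PIP	281	NPA	NPA	FHTR	QSAFW	29.83	9.00	0.41	0.415	6	Plas	CM
PruavSIP1;1	SIP	240	NPS	NPA	AVPN	MAAYW	25.18	9.82	0.35	0.896	5	Vacu	CM.VC
PruavSIP1;2	SIP	244	NPT	NPA	TVPN	MAAYW	25.88	9.52	0.22	0.755	6	Chlo	CM.VC
PruavSIP2;1	SIP	236	NPL	NPA	SHGS	FVAYW	25.80	9.52	0.53	0.538	4	Plas	CM
PruavTIP1;1	TIP	252	NPA	NPA	HIAV	TSAYW	25.94	5.54	0.18	0.769	6	Plas	VC
PruavTIP1;2	TIP	252	NPA	NPA	HIAV	TSAYW	26.08	4.78	0.25	0.884	6	Vacu	VC
PruavTIP1;3	TIP	252	NPA	NPA	HIAV	TSAYW	26.15	6.12	0.41	0.735	6	Plas	VC
PruavTIP2;1	TIP	248	NPA	NPA	HIGR	TSAYW	25.40	6.26	0.55	0.941	7	Plas	VC
PruavTIP2;2	TIP	248	NPA	NPA	HIGR	TSAYW	25.17	4.86	0.44	0.982	6	Plas	VC
PruavTIP3;1	TIP	256	NPA	NPA	HIGR	TAAYW	27.26	7.11	0.58	0.530	6	Plas	VC
PruavTIP4;1	TIP	249	NPA	NPA	HIAR	TSAYW	26.24	5.54	0.54	0.821	7	Vacu	VC
PruavTIP5;1	TIP	255	NPA	NPA	NVGC	VAAYW	25.84	6.81	0.06	0.842	6	Plas	CM.VC
PruavXIP1;1	XIP	304	SLV	SPA	VIVR	MCAFW	32.17	5.97	0.43	0.725	6	Plas	CM
PruavXIP2;1	XIP	314	NPV	NPA	ITVR	VCAFW	33.85	7.74	0.55	0.665	7	Plas	CM
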