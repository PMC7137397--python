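strain	genus	DGD	DGD_sd	GDGT-0	GDGT-0_sd	GDGT-1	GDGT-1_sd	GDGT-2	GDGT-2_sd	GDGT-3	GDGT-3_sd	GDGT-4	GDGT-4_sd	GMGT-0	GMGT-0_sd	GMGT-1	GMGT-1_sd	GTGT-0	GTGT-0_sd	GTGT-1	GTGT-1_sd
Palaeococcus ferrophilus	Palaeococcus	42.9	4.8	57.5	4.8	ND		ND		ND		ND		ND		ND		0.5	0.1	ND
Palaeococcus helgesonii	Palaeococcus	26.0	5.4	47.5	8.6	ND		ND		ND		ND		26.4	13.4	ND		0.2	0.1	ND
Palaeococcus pacificus	Palaeococcus	47.7	5.8	51.3	5.9	ND		ND		ND		ND		ND		ND		1.0	0.1	ND
Pyrococcus abyssi	Pyrococcus	16.5	1.4	83.4	1.3	ND		ND		ND		ND		ND		ND		0.1	0.2	ND
Pyrococcus endeavori ES4	Pyrococcus	35.4	0.4	64.5	0.4	ND		ND		ND		ND		ND		ND		0.1	0.0	ND
Pyrococcus furiosus	Pyrococcus	39.3	9.0	11.7	2.8	2.4	0.9	0.8	0.3	0.2	0.1	Traces		38.9	4.8	4.4	1.1	2.2	0.9	0.1	0.0
Pyrococcus glycovorans	Pyrococcus	34.3	13.1	65.3	13.3	ND		ND		ND		ND		ND		ND		0.4	0.2	ND
Pyrococcus horikoshii OT3	Pyrococcus	9.1	2.0	63.6	3.8	0.6	0.1	0.1	0.1	ND		ND		28.7	2.3	0.2	0.1	ND		ND
Pyrococcus horikoshii JA-1	Pyrococcus	8.2	1.3	63.3	4.6	5.1	1.4	1.6	0.4	0.1	0.1	ND		20.9	4.4	0.9	0.6	0.1	0.1	ND
Pyrococcus kukulkanii	Pyrococcus	33.3	10.5	65.9	10.5	0.1	0.1	ND		ND		ND		0.3	0.3	ND		0.4	0.1	ND
Pyrococcus woesei	Pyrococcus	32.4	14.8	65.4	15.9	ND		ND		ND		ND		0.4	0.2	ND		1.8	1.1	ND
Thermococcus acidaminovorans	Thermococcus	49.6	4.5	49.0	4.7	ND		ND		ND		ND		0.1	0.1	ND		1.4	0.2	ND
Thermococcus aegaeus	Thermococcus	60.1	11.1	36.8	10.9	ND		ND		ND		ND		ND		ND		0.6	0.2	ND
Thermococcus aggregans	Thermococcus	57.2	1.2	42.1	1.6	ND		ND		ND		ND		ND		ND		0.7	0.5	ND
Thermococcus alcaliphilus	Thermococcus	61.5	6.8	38.0	6.7	ND		ND		ND		ND		ND		ND		0.4	0.1	ND
Thermococcus atlanticus	Thermococcus	30.3	7.5	66.6	6.4	ND		ND		ND		ND		2.5	1.2	ND		0.6	0.2	ND
Thermococcus barophilus MP	Thermococcus	55.1	8.0	44.3	8.2	ND		ND		ND		ND		ND		ND		0.6	0.2	ND
Thermococcus barophilus CH1	Thermococcus	52.9	10.1	44.5	9.8	ND		ND		ND		ND		ND		ND		2.6	0.2	ND
Thermococcus barophilus CH5	Thermococcus	36.4	11.1	61.9	11.1	ND		ND		ND		ND		ND		ND		1.7	0.1	ND
Thermococcus barossii	Thermococcus	53.9	1.4	45.2	1.3	ND		ND		ND		ND		ND		ND		0.9	0.1	ND
Thermococcus celer	Thermococcus	60.1	4.0	37.4	3.7	ND		ND		ND		ND		2.3	0.3	ND		0.2	0.1	ND
Thermococcus celericrescens	Thermococcus	69.0	9.3	30.4	9.1	ND		ND		ND		ND		ND		ND		0.6	0.3	ND
Thermococcus chitonophagus	Thermococcus	54.7	4.7	43.9	4.8	0.7	0.1	0.3	0.3	Traces		ND		ND		ND		0.4	0.3	ND
Thermococcus cleftensis	Thermococcus	60.9	5.7	38.8	5.7	ND		ND		ND		ND		ND		ND		0.4	0.0	ND
Thermococcus coalescens	Thermococcus	79.9	1.5	19.9	1.6	ND		ND		ND		ND		ND		ND		0.3	0.2	ND
Thermococcus fumicolans	Thermococcus	42.0	2.6	57.9	2.6	ND		ND		ND		ND		ND		ND		0.1	0.1	ND
Thermococcus gammatolerans	Thermococcus	55.8	3.6	43.6	3.6	ND		ND		ND		ND		ND		ND		0.5	0.2	0.1	0.1
Thermococcus gorgonarius	Thermococcus	79.9	5.8	19.8	5.8	ND		ND		ND		ND		0.2	0.1	ND		0.2	0.1	ND
Thermococcus guaymasensis	Thermococcus	51.7	6.6	44.3	6.0	ND		ND		ND		ND		3.4	1.1	ND		0.6	0.1	ND
Thermococcus hydrothermalis	Thermococcus	56.6	13.1	42.6	12.9	ND		ND		ND		ND		ND		ND		0.8	0.1	ND
Thermococcus kodakarensis	Thermococcus	68.1	8.0	31.5	7.9	ND		ND		ND		ND		ND		ND		0.4	0.1	ND
Thermococcus litoralis	Thermococcus	62.4	5.8	35.5	5.2	1.0	0.2	0.7	0.1	0.1	0.1	ND		ND		ND		0.4	0.2	ND
Thermococcus marinus	Thermococcus	70.9	1.2	28.8	1.2	0.1	0.1	Traces		ND		ND		ND		ND		0.2	0.0	ND
Thermococcus nautili	Thermococcus	71.1	4.5	28.6	4.4	ND		ND		ND		ND		ND		ND		0.3	0.3	ND
Thermococcus onnurineus	Thermococcus	65.2	4.2	33.1	4.0	ND		ND		ND		ND		ND		ND		1.7	0.4	ND
Thermococcus pacificus	Thermococcus	59.1	7.1	40.6	6.9	ND		ND		ND		ND		ND		ND		0.3	0.2	ND
Thermococcus paralvinellae	Thermococcus	62.3	6.3	35.7	6.0	ND		ND		ND		ND		ND		ND		2.0	0.3	ND
Thermococcus peptonophilus	Thermococcus	59.2	5.9	39.8	6.2	ND		ND		ND		ND		0.6	0.3	ND		0.5	0.0	ND
Thermococcus piezophilus	Thermococcus	65.7	4.4	33.1	4.2	ND		ND		ND		ND		ND		ND		1.2	0.3	ND
Thermococcus prieurii	Thermococcus	42.0	2.5	57.5	2.5	ND		ND		ND		ND		Traces		ND		0.5	0.1	ND
Thermococcus profundus	Thermococcus	39.1	7.3	60.7	7.1	ND		ND		ND		ND		0.1	0.1	ND		0.1	0.0	ND
Thermococcus radiotolerans	Thermococcus	45.6	13.2	51.5	13.8	ND		ND		ND		ND		0.1	0.1	ND		2.8	0.7	ND
Thermococcus sibiricus	Thermococcus	44.3	2.9	55.5	3.0	ND		ND		ND		ND		ND		ND		0.2	0.1	ND
Thermococcus siculi	Thermococcus	38.9	6.1	59.9	6.2	ND		ND		ND		ND		0.6	0.2	ND		0.6	0.2	ND
Thermococcus sp. AM4	Thermococcus	59.1	12.4	39.9	12.1	ND		ND		ND		ND		ND		ND		1.0	0.3	ND
Thermococcus sp. DT4	Thermococcus	50.6	2.8	47.8	2.5	ND		ND		ND		ND		ND		ND		1.4	0.2	0.2	0.2
Thermococcus sp. P6	Thermococcus	39.8	6.7	55.9	6.0	2.4	0.5	1.1	0.2	0.2	0.0	Traces		0.5	0.1	Traces		0.2	0.0	Traces
Thermococcus stetteri	Thermococcus	35.6	5.7	63.3	5.9	ND		ND		ND		ND		ND		ND		1.1	0.3	ND
Thermococcus thioreducens	Thermococcus	71.1	6.2	28.1	6.5	ND		ND		ND		ND		ND		ND		0.8	0.3	ND
Thermococcus waiotapuensis	Thermococcus	36.4	8.1	22.1	0.5	ND		ND		ND		ND		40.6	8.2	ND		0.8	0.0	ND
Thermococcus zilligii	Thermococcus	42.5	2.2	56.8	2.3	ND		ND		ND		ND		ND		ND		0.7	0.1	ND
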