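drug	pt	n	ror	ror05	prr	chi2	ic	ic025	ebgm	ebgm05
lenvatinib	Feeding disorder	14	3.243	1.919	3.24	19.45	1.69	1.00	3.23	2.08
lenvatinib	Total	14	3.243	1.919	3.24	19.45	1.69	1.00	3.23	2.08
sorafenib	Confusional state	202	2.490	2.167	2.46	175.07	1.30	1.13	2.46	2.19
sorafenib	Disorientation	58	2.803	2.165	2.79	64.96	1.47	1.14	2.79	2.25
sorafenib	Feeding disorder	47	6.652	4.990	6.63	217.62	2.72	2.04	6.59	5.18
sorafenib	Mental status changes	33	2.160	1.534	2.16	19.32	1.11	0.79	2.15	1.62
sorafenib	Aphonia	16	2.639	1.615	2.64	14.63	1.40	0.85	2.63	1.75
sorafenib	Total	356	2.724	2.454	2.71	385.01	1.44	1.30	2.71	2.48
cabozantinib	Feeding disorder	119	12.476	10.400	12.39	1212.78	3.61	3.01	12.18	10.46
cabozantinib	Hypersomnia	66	3.512	2.756	3.50	115.00	1.80	1.41	3.49	2.85
cabozantinib	Aphonia	49	5.946	4.487	5.93	194.34	2.56	1.93	5.89	4.65
cabozantinib	Laziness	4	3.627	1.357	3.63	5.18	1.85	0.69	3.61	1.59
cabozantinib	Total	238	6.313	5.555	6.29	1050.34	2.64	2.34	6.24	5.61
sunitinib	Feeding disorder	88	5.557	4.501	5.54	318.79	2.45	1.99	5.48	4.59
sunitinib	Mutism	5	2.808	1.165	2.81	4.12	1.48	0.62	2.80	1.34
sunitinib	Thyrotoxic crisis	5	4.299	1.781	4.30	9.47	2.09	0.87	4.26	2.04
sunitinib	Total	98	5.211	4.269	5.21	328.84	2.37	1.94	5.15	4.36
Total	Total	706	2.957	1.465	2.95	907.82	1.56	0.77	2.94	1.63
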