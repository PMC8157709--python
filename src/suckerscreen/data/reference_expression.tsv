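gene_id	group	ea	ve	control
NtLs	homolog	1.16	62.97	1.14
NtBl1	homolog	12.80	108.85	8.43
NtBl2	homolog	ND	ND	ND
NtBl3	homolog	11.88	23.20	10.26
NtREV	homolog	110.74	167.99	305.61
NtCUC1	homolog	4.24	10.32	8.38
NtCUC2	homolog	ND	ND	ND
NtCUC3	homolog	ND	ND	ND
NtCUC4	homolog	ND	ND	ND
NtFHY3	homolog	23.49	36.90	46.59
NtLOM1	homolog	36.69	49.15	65.87
NtLOF1	homolog	30.27	60.57	25.56
EA1	screen	32.93	2.30	ND
EA2	screen	20.13	9.70	1.48
EA3	screen	22.56	1.77	ND
EA4	screen	43.22	2.50	1.19
EA5	screen	14.41	ND	ND
EA6	screen	22.78	ND	ND
EA7	screen	12.14	ND	ND
EA8	screen	43.57	ND	1.47
EA9	screen	14.03	ND	ND
EA10	screen	51.93	8.72	1.25
EA11	screen	19.63	1.70	1.62
VE1	screen	39.71	49.37	3.79
VE2	screen	26.70	32.21	0.69
VE3	screen	6.51	49.14	ND
VE4	screen	ND	10.94	ND
VE5	screen	20.88	79.27	3.12
VE6	screen	2.61	31.26	ND
VE7	screen	ND	73.71	4.97
VE8	screen	5.93	13.38	ND
VE9	screen	5.06	14.07	ND
VE10	screen	9.42	21.58	1.86
VE11	screen	ND	13.62	ND
VE12	screen	19.79	133.95	11.71
VE13	screen	5.68	19.24	ND
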