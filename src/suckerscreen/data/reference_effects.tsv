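construct	trait	mean	sd	marked
NtLs	expression	0.50	0.08	0
NtLs	primary_n	1.00	0.00	0
NtLs	primary_wt	1.28	0.15	0
NtLs	secondary_n	0.13	0.09	1
NtLs	secondary_wt	0.10	0.06	1
NtBl1	expression	0.31	0.05	0
NtBl1	primary_n	1.02	0.06	0
NtBl1	primary_wt	1.21	0.18	0
NtBl1	secondary_n	0.00	0.00	1
NtBl1	secondary_wt	0.00	0.00	1
NtBl2	expression	0.19	0.04	0
NtBl2	primary_n	1.00	0.00	0
NtBl2	primary_wt	1.13	0.15	0
NtBl2	secondary_n	1.00	0.10	0
NtBl2	secondary_wt	1.46	1.65	0
NtBl3	expression	0.30	0.09	0
NtBl3	primary_n	1.00	0.00	0
NtBl3	primary_wt	1.45	0.48	0
NtBl3	secondary_n	0.88	0.46	0
NtBl3	secondary_wt	0.77	0.12	0
NtREV	expression	0.62	0.10	0
NtREV	primary_n	1.00	0.00	0
NtREV	primary_wt	0.98	0.09	0
NtREV	secondary_n	0.06	0.10	1
NtREV	secondary_wt	0.03	0.04	1
NtCUC1	expression	0.16	0.07	0
NtCUC1	primary_n	1.00	0.00	0
NtCUC1	primary_wt	1.05	0.12	0
NtCUC1	secondary_n	0.91	0.18	0
NtCUC1	secondary_wt	0.57	0.10	0
NtCUC2	expression	0.53	0.04	0
NtCUC2	primary_n	1.00	0.00	0
NtCUC2	primary_wt	1.14	0.26	0
NtCUC2	secondary_n	0.97	0.12	0
NtCUC2	secondary_wt	1.06	0.40	0
NtCUC3	expression	0.17	0.10	0
NtCUC3	primary_n	1.00	0.00	0
NtCUC3	primary_wt	0.96	0.17	0
NtCUC3	secondary_n	1.08	0.01	0
NtCUC3	secondary_wt	0.71	0.26	0
NtCUC4	expression	0.69	0.03	0
NtCUC4	primary_n	1.00	0.00	0
NtCUC4	primary_wt	0.91	0.04	0
NtCUC4	secondary_n	1.05	0.09	0
NtCUC4	secondary_wt	0.75	0.19	0
NtFHY3	expression	0.31	0.17	0
NtFHY3	primary_n	1.00	0.00	0
NtFHY3	primary_wt	0.94	0.08	0
NtFHY3	secondary_n	1.03	0.11	0
NtFHY3	secondary_wt	1.12	0.62	0
NtLOM1	expression	0.38	0.06	0
NtLOM1	primary_n	1.00	0.00	0
NtLOM1	primary_wt	1.09	0.15	0
NtLOM1	secondary_n	1.72	1.97	0
NtLOM1	secondary_wt	2.56	3.99	0
NtLOF1	expression	0.38	0.11	0
NtLOF1	primary_n	1.01	0.02	0
NtLOF1	primary_wt	1.67	0.15	0
NtLOF1	secondary_n	0.28	0.30	0
NtLOF1	secondary_wt	0.64	0.58	0
EA1	expression	0.09	0.03	0
EA1	primary_n	1.00	0.00	0
EA1	primary_wt	1.14	0.16	0
EA1	secondary_n	0.97	0.15	0
EA1	secondary_wt	1.21	0.34	0
EA2	expression	0.28	0.16	0
EA2	primary_n	1.00	0.00	0
EA2	primary_wt	1.17	0.35	0
EA2	secondary_n	1.34	0.82	0
EA2	secondary_wt	1.65	1.59	0
EA3	expression	0.16	0.03	0
EA3	primary_n	1.00	0.00	0
EA3	primary_wt	0.93	0.09	0
EA3	secondary_n	0.68	0.16	0
EA3	secondary_wt	1.42	1.53	0
EA4	expression	0.35	0.17	0
EA4	primary_n	1.00	0.00	0
EA4	primary_wt	1.16	0.28	0
EA4	secondary_n	1.14	0.41	0
EA4	secondary_wt	1.09	0.38	0
EA5	expression	0.10	0.04	0
EA5	primary_n	1.00	0.00	0
EA5	primary_wt	1.04	0.07	0
EA5	secondary_n	4.05	2.21	0
EA5	secondary_wt	18.88	28.34	0
EA6	expression	0.80	0.22	0
EA6	primary_n	1.00	0.00	0
EA6	primary_wt	1.01	0.26	0
EA6	secondary_n	1.04	0.27	0
EA6	secondary_wt	1.30	0.80	0
EA7	expression	0.10	0.01	0
EA7	primary_n	1.00	0.00	0
EA7	primary_wt	1.02	0.17	0
EA7	secondary_n	0.83	0.76	0
EA7	secondary_wt	0.77	0.70	0
EA8	expression	0.02	0.02	0
EA8	primary_n	1.00	0.00	0
EA8	primary_wt	1.08	0.36	0
EA8	secondary_n	1.14	0.11	0
EA8	secondary_wt	1.21	0.20	0
EA9	expression	0.17	0.12	0
EA9	primary_n	1.00	0.00	0
EA9	primary_wt	0.95	0.17	0
EA9	secondary_n	1.10	0.77	0
EA9	secondary_wt	1.16	0.74	0
EA10	expression	0.43	0.08	0
EA10	primary_n	1.00	0.00	0
EA10	primary_wt	1.33	0.16	0
EA10	secondary_n	1.59	0.99	0
EA10	secondary_wt	0.96	0.21	0
EA11	expression	0.56	0.08	0
EA11	primary_n	1.00	0.00	0
EA11	primary_wt	0.98	0.27	0
EA11	secondary_n	0.98	0.09	0
EA11	secondary_wt	1.52	0.92	0
VE1	expression	0.58	0.06	0
VE1	primary_n	1.00	0.00	0
VE1	primary_wt	0.99	0.30	0
VE1	secondary_n	1.10	0.16	0
VE1	secondary_wt	1.27	0.51	0
VE2	expression	0.51	0.02	0
VE2	primary_n	1.00	0.00	0
VE2	primary_wt	1.04	0.12	0
VE2	secondary_n	1.09	0.17	0
VE2	secondary_wt	0.95	0.54	0
VE3	expression	1.51	0.05	0
VE3	primary_n	1.00	0.00	0
VE3	primary_wt	1.16	0.21	0
VE3	secondary_n	1.02	0.45	0
VE3	secondary_wt	0.97	0.35	0
VE4	expression	0.32	0.04	0
VE4	primary_n	1.00	0.00	0
VE4	primary_wt	1.27	0.31	0
VE4	secondary_n	0.80	0.38	0
VE4	secondary_wt	0.95	0.64	0
VE5	expression	0.41	0.06	0
VE5	primary_n	1.00	0.00	0
VE5	primary_wt	1.00	0.17	0
VE5	secondary_n	1.30	0.74	0
VE5	secondary_wt	1.41	0.84	0
VE6	expression	0.35	0.14	0
VE6	primary_n	1.00	0.00	0
VE6	primary_wt	0.73	0.12	0
VE6	secondary_n	2.06	0.56	0
VE6	secondary_wt	4.57	3.20	0
VE7	expression	0.08	0.02	0
VE7	primary_n	1.00	0.00	0
VE7	primary_wt	1.49	0.30	0
VE7	secondary_n	0.33	0.09	1
VE7	secondary_wt	0.26	0.11	1
VE8	expression	0.14	0.06	0
VE8	primary_n	1.00	0.00	0
VE8	primary_wt	1.01	0.28	0
VE8	secondary_n	1.41	0.43	0
VE8	secondary_wt	0.87	0.39	0
VE9	expression	0.62	0.08	0
VE9	primary_n	1.00	0.00	0
VE9	primary_wt	0.98	0.10	0
VE9	secondary_n	1.03	0.16	0
VE9	secondary_wt	0.90	0.12	0
VE10	expression	0.42	0.04	0
VE10	primary_n	1.00	0.00	0
VE10	primary_wt	0.97	0.25	0
VE10	secondary_n	1.16	0.62	0
VE10	secondary_wt	1.79	1.29	0
VE11	expression	0.70	0.07	0
VE11	primary_n	1.00	0.00	0
VE11	primary_wt	1.07	0.28	0
VE11	secondary_n	0.58	0.56	0
VE11	secondary_wt	0.42	0.43	0
VE12	expression	0.18	0.06	0
VE12	primary_n	1.00	0.00	0
VE12	primary_wt	1.22	0.12	0
VE12	secondary_n	0.29	0.41	0
VE12	secondary_wt	0.05	0.08	1
VE13	expression	0.14	0.05	0
VE13	primary_n	1.00	0.00	0
VE13	primary_wt	1.03	0.21	0
VE13	secondary_n	1.03	0.12	0
VE13	secondary_wt	1.86	0.94	0
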