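i	pds_i	sd_i	j	pds_j	sd_j	mi	highlighted
29	0.25	0.16	98	0.43	0.11	0.64260	1
42	0.21	0.10	117	0.24	0.09	0.703328	1
44	0.26	0.13	122	0.36	0.05	0.593079	1
46	0.27	0.11	115	0.23	0.09	0.577762	1
58	0.38	0.18	68	0.60	0.12	0.615481	0
62	0.44	0.19	116	0.26	0.10	0.583716	0
67	0.56	0.14	124	0.48	0.06	0.608395	1
70	0.68	0.10	96	0.47	0.11	0.603931	1
99	0.42	0.10	122	0.36	0.05	0.603343	0
118	0.27	0.09	125	0.52	0.07	0.6989	0
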