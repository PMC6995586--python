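i	pds_i	sd_i	j	pds_j	sd_j	di	highlighted
8	0.33	0.12	86	0.59	0.05	0.108738	0
10	0.28	0.09	138	0.63	0.09	0.122847	1
15	0.24	0.05	28	0.25	0.16	0.125331	1
16	0.25	0.05	89	0.54	0.04	0.109716	0
17	0.27	0.07	100	0.41	0.09	0.0900074	0
28	0.25	0.16	99	0.42	0.10	0.131024	0
29	0.25	0.16	98	0.43	0.11	0.095733	0
31	0.25	0.16	115	0.23	0.09	0.0851411	0
39	0.21	0.11	83	0.67	0.09	0.0948818	1
40	0.21	0.11	137	0.62	0.12	0.249519	1
42	0.21	0.10	119	0.28	0.07	0.105276	1
44	0.26	0.13	56	0.34	0.17	0.0880899	0
46	0.27	0.11	116	0.26	0.10	0.0962272	1
59	0.38	0.19	67	0.56	0.14	0.107917	0
60	0.39	0.19	113	0.22	0.08	0.156108	1
69	0.65	0.13	127	0.58	0.09	0.126032	1
118	0.27	0.09	125	0.52	0.07	0.100409	0
122	0.36	0.05	128	0.58	0.09	0.156898	1
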