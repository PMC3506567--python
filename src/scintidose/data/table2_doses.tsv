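patient	side	sex	kidney_thickness_cm	mass_kg	trunk_thickness_cm	cycle1	cycle2	cycle3	cycle4	cycle5
1	right	M	5.5	0.129	27	0.68	0.87	0.72	0.51	ND
1	left	M	NA	NA	NA	NA	NA	NA	NA	ND
2	right	M	6.8	0.168	17	0.38	0.48	0.45	0.37	0.52
2	left	M	5.7	0.194	17	0.43	0.70	0.57	0.52	0.33
3	right	F	6.6	0.190	19	1.09	0.76	0.82	0.84	ND
3	left	F	5.27	0.154	19	0.91	0.68	0.76	0.86	ND
4	right	F	NA	NA	NA	NA	NA	NA	NA	ND
4	left	F	4.3	0.113	21	0.86	0.77	0.84	0.95	ND
5	right	M	NA	NA	NA	NP	NP	NP	NP	NP
5	left	M	6.4	0.234	23	0.74	0.57	0.76	ND	ND
6	right	M	5.4	0.135	23	0.89	ND	ND	ND	ND
6	left	M	5.6	0.137	22	0.56	ND	ND	ND	ND
7	right	M	6.6	0.190	24	0.60	0.60	0.62	ND	ND
7	left	M	5.8	0.161	25	0.78	0.79	0.69	ND	ND
8	right	M	5.5	0.123	22	0.60	0.60	0.62	1.1	ND
8	left	M	5.0	0.152	23	0.78	0.79	0.69	0.74	ND
9	right	F	5.4	0.135	16	0.96	1.2	ND	ND	ND
9	left	F	3.0	0.054	18	1.7	2.4	ND	ND	ND
10	right	F	5.9	0.138	18	1.2	1.3	ND	ND	ND
10	left	F	5.6	0.149	17	0.91	1.2	ND	ND	ND
11	right	M	5.4	0.157	20	0.77	0.94	0.92	1.1	ND
11	left	M	6.3	0.177	20	0.69	0.73	0.94	0.87	ND
12	right	F	6.3	0.137	16	0.73	0.61	0.59	ND	ND
12	left	F	5.8	0.168	17	0.74	0.68	0.78	ND	ND
13	right	F	5.1	0.131	19	0.59	0.87	0.79	ND	ND
13	left	F	5.1	0.107	20	NA	NA	NA	ND	ND
14	right	M	3.7	0.087	18	NA	NA	NA	ND	ND
14	left	M	4.7	0.088	19	0.94	1.0	0.97	ND	ND
15	right	F	5.7	0.159	19	1.3	ND	ND	ND	ND
15	left	F	5.2	0.188	18	1.3	ND	ND	ND	ND
16	right	M	6.5	0.215	25	0.63	0.59	0.61	0.56	ND
16	left	M	6.3	0.231	26	0.52	0.52	0.47	0.51	ND
17	right	M	5.6	0.187	23	0.50	0.47	0.50	0.63	ND
17	left	M	6.4	0.215	24	0.49	0.52	0.50	0.52	ND
18	right	M	5.3	0.132	17	0.85	0.88	0.94	ND	ND
18	left	M	5.2	0.117	19	1.0	1.1	1.0	ND	ND
19	right	F	NA	NA	NA	NA	NA	NA	ND	ND
19	left	F	4.5	0.094	21	1.2	0.97	1.3	ND	ND
20	right	M	5.6	0.184	23	0.66	0.56	0.57	0.57	ND
20	left	M	5.6	0.153	23	0.77	0.67	0.68	0.61	ND
21	right	F	5.9	0.091	16	1.5	1.6	ND	ND	ND
21	left	F	4.7	0.098	18	1.3	1.3	ND	ND	ND
22	right	M	5.6	0.162	23	0.73	0.74	0.73	0.64	ND
22	left	M	5.6	0.194	24	0.74	0.72	0.66	0.60	ND
23	right	F	NA	NA	NA	NA	NA	NA	ND	ND
23	left	F	4.7	0.124	20	0.70	0.83	0.84	ND	ND
24	right	M	NA	NA	NA	NA	NA	NA	NA	ND
24	left	M	5.6	0.167	24	0.86	0.74	0.80	0.73	ND
25	right	M	5.9	0.186	24	0.55	0.48	0.44	0.46	ND
25	left	M	5.9	0.209	26	0.52	0.47	0.40	0.46	ND
26	right	M	7.0	0.189	32	1.3	1.4	ND	ND	ND
26	left	M	5.5	0.145	30	1.5	1.3	ND	ND	ND
27	right	M	5.6	0.156	23	1.2	1.3	1.2	ND	ND
27	left	M	6.1	0.200	22	0.68	1.2	1.3	ND	ND
28	right	F	4.4	0.111	18	1.0	1.0	ND	ND	ND
28	left	F	5.1	0.158	19	1.1	1.0	ND	ND	ND
29	right	M	NA	NA	NA	NA	NA	NA	NA	ND
29	left	M	5.6	0.181	21	0.59	0.67	0.65	0.81	ND
30	right	M	6.1	0.192	21	0.51	0.48	0.43	ND	ND
30	left	M	NA	NA	NA	NA	NA	NA	ND	ND
31	right	F	NA	NA	NA	NA	NA	ND	ND	ND
31	left	F	4.9	0.118	18	0.58	0.49	ND	ND	ND
32	right	M	6.2	0.155	24	0.95	NA	ND	ND	ND
32	left	M	6.4	0.168	24	0.72	0.75	ND	ND	ND
33	right	F	5.3	0.116	23	1.0	ND	ND	ND	ND
33	left	F	5.3	0.161	22	0.65	ND	ND	ND	ND
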