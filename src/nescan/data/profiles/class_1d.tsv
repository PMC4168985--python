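#class 1d
#template SEQLAELQAGLDLN
#standard_score 5
#phi 4,7,11,13
A	4.91	5.21	4.67	-0.65	5	5.98	1.31	5.73	5	4.99	1.67	3.06	0.46	4.64
C	5.97	4.82	3.5	-0.8	3.05	4.03	1.08	5.8	4.14	3.73	-0.29	3.25	1.33	4.68
D	3.29	5.41	4.78	1.4	5.97	4.88	1.05	4.11	3.25	4.51	-0.84	5	-0.26	5.13
E	4.52	5	5.58	-0.97	5.86	5	0.91	4.35	5.62	3.04	1.97	3.82	-0.34	5.79
F	4.19	4.05	5.56	3.29	4.87	4.64	4.95	5.47	4.71	5.97	5.64	4.29	5.73	4.93
G	3.62	3.66	3.96	-0.22	3.63	5.04	-0.41	4.21	4.86	5	0.67	3.08	0.17	3.71
H	5.65	5.17	3.47	-0.88	4.76	5.7	-0.36	3.72	4.81	3.12	0.95	5.37	0.28	3.69
I	4.62	4.13	3.81	3.78	3.7	5.76	5.88	3.56	3.08	4.22	4.11	5.44	5.47	5.82
K	4.84	4.13	5.05	1.53	4.97	4.21	0.32	3.27	3.74	4.75	1.5	4.04	1.62	5.38
L	3.86	4.92	4.69	5	3.11	3.06	5	3.03	3.62	4.58	5	5.04	5	3.88
M	4.67	4.05	4.63	3.94	5.21	4.35	4.65	4.8	3.32	4.97	4.61	3	4.44	5.08
N	5.2	5.03	5.4	-0.16	5.68	5.62	0.3	5.96	3.53	4.15	1.11	4.09	0.98	5
P	0.14	-1.1	0.27	1.17	-1.36	0.56	-0	-1.46	0.04	-0.71	0.31	-1.32	0.54	-0.62
Q	3.79	4.52	5	1.3	3.73	5.24	-0.89	5	4.41	5.26	0.15	3.65	-0.55	5.19
R	3.98	4.92	4.46	1.3	3.25	3.87	0.17	5.35	4.88	5.83	0.1	4.18	-0.2	3.77
S	5	4.9	4.27	-0.4	5.9	5.22	1.88	3.86	3.81	3.25	-0.13	3.12	-0.41	5.6
T	4.37	4.01	5.17	-0.98	4.38	4.36	-0.79	4.21	5.79	5.5	1.97	5.39	1.61	5.04
V	4.48	4.98	3.77	3.26	5.23	5.29	3.33	5.04	3.54	4.44	4.75	3.91	4.07	5.6
W	4.8	3.67	5.76	0.24	5.84	4.96	-1	3.77	5.2	3.31	1.72	4.34	-0.7	3.71
Y	5.36	3.78	4.83	0.12	3.78	3.4	-0.64	4.23	5.35	5.59	0.45	3.8	-0.56	5.48
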