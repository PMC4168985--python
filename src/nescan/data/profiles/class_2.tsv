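#class 2
#template SEQLELSELELNSD
#standard_score 3
#phi 4,6,9,11
A	3.52	2.69	1.76	-1.84	3.01	-1.29	2.72	3.47	-1.28	1.62	-1.86	1.52	3.59	1.12
C	3.08	1.8	2.2	-1.83	2.68	-2.94	2.3	1.31	-2.23	3.67	-0.23	1.45	2.72	3.08
D	1.65	3.09	1.89	-1.76	3.95	-2.46	3.09	2.88	-1.46	3.91	-0.09	2.66	3.75	3
E	1.38	3	3.68	-2.68	3	-1.84	1.5	3	-2.68	3	-1.18	2.74	2	3.49
F	2.13	3.91	2.37	3.71	2.45	1.77	2.23	2.44	2.17	2.64	1.62	3.89	1.95	3.21
G	3.26	2.5	2.06	-0.44	1.96	-0.21	1.54	2.07	-0.31	2.34	-2.65	2.91	1.93	3.79
H	3.21	1.57	2.13	-2.06	2.34	-1.61	3.83	3.52	-0.95	2.8	-1.91	3.33	3.75	2.88
I	2.24	2.39	2.83	3.38	1.24	3.26	2.34	2.11	1.05	1.66	2.99	1.2	2.23	1.23
K	2.93	3.14	2.42	-2.04	2.51	-0.61	1.09	3.93	-1.23	2.43	-0.2	2.4	3.56	2.37
L	3.47	3.47	1.36	3	1.39	3	1.16	3.91	3	3.66	3	1.18	3.12	3
M	1.2	3.61	2.49	3.34	3.55	1.67	3	2.99	1.36	3.38	1.06	1.34	2.6	2.13
N	2.61	3.3	3.23	-1.57	2.22	-0.99	1.86	3.03	-1.15	1.3	-2.53	3	3.35	1.87
P	-3.62	-3.58	-1.02	-0.54	-2.01	-1.53	-1.86	-3.15	-2.53	-3.09	-0.08	-2.15	-1.03	-1.83
Q	3.48	1.89	3	-1.74	2.33	-1.75	2.48	1.48	-0.49	1.18	-2.77	2.02	3.36	2.87
R	1.66	3.09	2.21	-2.72	1.8	-1.71	2.71	1.83	-1.38	1.57	-0.19	2.65	3.17	3.97
S	3	2.38	3.52	-0.85	1.34	-1.89	3	2.38	-2.64	2.85	-1.15	3.3	3	2.44
T	2.1	2.61	2.95	-0.95	2.55	-1.76	3.4	2.21	-2.59	3.26	-2.75	3.45	2.76	1.58
V	1.8	3.59	1.22	2.31	2.35	3.45	2.55	1.61	1.29	3.36	1.39	2.99	1.95	3.89
W	3.39	1.33	3.07	-0.16	1.76	-2.64	1.12	3.59	-2.5	1.36	-2.81	3.23	3.92	1.73
Y	2.68	1.14	3.96	-2.07	2.06	-2.07	3.5	1.37	-1.02	3.27	-0.71	1.28	1.05	3.81
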