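#class 1c
#template SELAEKLQAGLDLN
#standard_score 8
#phi 3,7,11,13
A	6.94	6.59	4.15	8	8.97	6.38	3.47	7.13	8	6.75	4.53	8.3	2.5	7.85
C	6.67	6.11	4.15	7.56	6.44	8.19	4.17	7.75	7.48	7.64	4	6.14	3.71	8.7
D	6.55	8.54	4.46	6.49	7.96	7.36	4.98	8.4	8.47	6.14	3.9	8	2.27	6.86
E	8.58	8	3.33	8.17	8	7.59	3.4	7.75	6.99	7.32	3.27	8.4	4.81	7.78
F	8.57	6.63	6.48	8.72	6.67	7.29	8.41	8.02	7.55	6.09	8.67	6.54	6.85	8.33
G	6.31	7.22	4.95	6.24	8.73	6.09	2.23	6.78	6.57	8	3.19	8.92	4.17	7.72
H	6.87	6.49	3.89	6.52	8.18	6.35	4.25	7.25	7.1	7.92	3.92	6.04	4.34	7.22
I	7.98	6.21	7.79	8.3	8.27	7.53	8.39	7.86	7.39	8.83	6.81	8.62	6.24	7.8
K	8.1	6.07	2.22	6.18	6.77	8	2.13	7.05	8.85	8.43	2.33	6.93	3.1	6.48
L	7.32	6.03	8	8.04	8.11	7.25	8	8.39	8.25	8.01	8	7.49	8	8.45
M	7.44	7.85	6.06	8.22	8.38	6.65	7.09	8.55	6.78	7.22	7.95	7.53	8.27	6.78
N	8.22	6.99	2.43	8.69	8.69	7.72	2.59	6.04	8.8	6.34	4.27	6.17	4.47	8
P	2.16	1.69	3.11	1.83	1.39	2.7	4.5	3.55	1.33	2.92	3.64	3.96	2.18	3.33
Q	8.88	7.38	3.7	7.11	6.3	7.53	4.92	8	8.6	8.22	2.25	7.78	2.75	8.53
R	6.93	7.89	2.42	6.28	7.93	7.85	2.57	7.91	8.27	8.06	3.48	8.72	2.4	8.05
S	8	6.73	3.57	6.8	7.2	8.93	2.8	8.72	6.44	6.69	3.22	7.07	2.79	6.62
T	6.76	6.39	4.99	6.46	8.64	8.15	4.82	6.86	6.96	7.48	2.49	8.93	3.16	8.83
V	6.17	8.01	8.96	7.54	7.04	7.86	7.54	7.01	6.33	6.91	7.24	6.14	7.93	7.72
W	8.77	6.84	4.04	6.08	7.82	8.1	3.72	7.28	7.94	7.06	3.87	8.93	2.26	6.88
Y	7.95	8.54	3.95	8.27	7.63	6.8	4.57	7.51	8.32	7.95	3.59	8.84	4.02	7.22
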