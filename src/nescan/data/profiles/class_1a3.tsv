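#class 1a3
#template LNELAQKLAGLDLN
#standard_score 8
#phi 1,4,8,11,13
A	4.3	7.52	7.39	2.4	8	7.76	8.88	3.15	8	6.68	3.69	8.2	3	6.57
C	3.57	7.11	6.28	3.84	7.53	8.34	7.13	4.53	6.7	8.35	2.26	7.77	4.43	6.93
D	2.17	6.17	7.48	3.03	7.63	7.15	7.09	3.28	6.46	6.25	4.79	8	2.48	6.83
E	2.36	6.75	8	4.1	6.28	6.46	8.07	3.87	7.49	8.52	2.93	6.94	3.39	6.75
F	6.88	8.52	6.28	8.7	8.64	7.82	6.81	6.89	6.96	8.14	8.66	7.4	8.95	6.11
G	2.98	8.45	6.27	3.91	7.81	7.21	7.1	3.69	8.55	8	4.8	6.81	3.93	8.87
H	2.41	8	6.65	2.94	6.32	7.21	6.92	2.24	7.39	6.13	3.56	8.21	3.33	7.53
I	7.09	7.41	8.1	7.95	8.22	6.26	8.09	8.31	6.68	6.75	6.74	6.21	8.81	6.98
K	3.91	8.91	6.54	2.84	6.34	7.26	8	3.43	7.29	6.54	4.34	8.19	3.2	8.64
L	8	8.52	7.71	8	7.14	6.16	7.14	8	6.67	7.94	8	8.5	8	6.07
M	8.42	6.74	7.81	7.45	8.01	8.71	8.99	8.26	8.11	7.41	8.76	6.74	6.32	6.32
N	2.21	8	8.9	3.18	7.4	7.12	7.92	3.29	8.92	7.72	3.52	7.08	2.11	8
P	3.63	2.13	3.08	2.89	2.64	1.05	1.26	3.37	2.43	1.18	2.63	1.6	4.45	1.12
Q	3.09	8.36	8.32	4.28	7.87	8	6.87	4.73	6.71	8.94	4.99	8.63	2.22	6.01
R	3.15	7.11	6.1	4.37	7.1	7.32	6.07	2.9	8.44	6.31	3.9	6.47	3.3	7.83
S	2.24	7.41	7.93	3.49	7.14	7.02	8.73	4.93	7.09	7.99	3.35	8.74	2.25	8.15
T	4.16	7.55	8.94	2.71	6.49	6.1	8.76	3.42	6.26	7.59	4.82	6.28	2.94	7.06
V	7.06	8.71	6.14	8.98	6.55	7.96	8.94	6.3	6.46	8.97	7.52	6.11	6.84	8.78
W	4.29	8.14	8.72	3.48	8.98	6.3	7.44	3.43	7.11	8.86	3.67	8.44	4.34	8.27
Y	2.96	7.19	6.47	4.27	7.81	6.7	7.78	4.14	8.5	7.44	3.22	6.2	4.78	8.96
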