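#class 1b
#template PSSELAKLAGLDLN
#standard_score 4
#phi 5,8,11,13
A	2.48	4.76	4.07	4.34	0.59	4	3.36	-1.19	4	2.39	-1.97	3.47	0.35	4.35
C	3.76	2.44	2.52	2.23	-0.31	2.47	4	-1.16	3.56	4.98	-0.25	4.65	-1.35	4.26
D	4.47	3.84	2.17	2.6	-1.65	3.16	2.19	-0.63	4.33	2.51	-0.5	4	-1.31	2.8
E	2.89	2.16	2.49	4	-1.71	3.64	3.1	-1.55	3.47	3.49	-0.33	2.79	-0.14	2.42
F	4.05	4.23	2.71	2.65	3.98	2.88	2.45	2.4	3.92	2.23	2.03	2.48	2.21	4.05
G	3.39	3.72	3.08	2.9	-0.79	2.5	2.56	0.56	2.44	4	0.99	2.51	-1.94	2.58
H	4.67	2.38	3.69	4.03	0.77	2.26	3.92	0.44	2.19	4.26	-0.64	3.05	-0.93	3.26
I	3.69	2.34	4.74	2.89	4.75	3.36	3.98	2.67	4.53	4	3.13	2.48	3.59	4.21
K	4.98	3.57	3.05	2.96	0.27	3.59	4	0.72	3.59	3.17	0.9	4.36	0.49	3.48
L	2.73	3.48	3.9	4.46	4	2.92	2.98	4	2.15	4.49	4	4.85	4	4.32
M	2.33	3.62	3.99	2.35	3.1	2.03	4.56	2.36	4.28	4.18	4.76	4.98	4.08	2.51
N	3.04	4.93	2.85	2.12	0.7	3.42	4.34	-1.48	4.28	3.57	-0.25	4.11	0.81	4
P	4	-0.15	-0.41	-1.53	0.86	-1.1	-0.38	-0.03	-2.02	-1.51	-0.64	-1.9	0.01	-1.7
Q	3.62	2.89	4.95	4.7	0.24	3.74	3.13	-1.92	4.11	3.86	-1.4	4.4	-1.42	3.61
R	4.77	2.22	4.99	4.03	-0.81	3.44	4.21	-1.69	4.88	2.25	0.46	3.32	-0.93	2.33
S	4.98	4	4	3.88	-1.21	3.36	2.8	-0.39	3.76	2.75	-1.05	2.11	-0.73	3.67
T	4.77	4.44	4.47	4.67	0.34	2.99	2.7	0.14	4.63	3.61	-1.16	4.91	0.56	3.19
V	2.49	2.79	3	3.59	4.37	3.78	2.09	4.64	2.33	2.91	4.11	2.3	3.9	4.73
W	3.77	2.43	4.41	2.34	0.4	2.58	4.23	-0.04	2.27	3.68	-0.87	2.15	-1.25	2.43
Y	4.18	3.81	3.13	3.13	0.87	4.68	2.48	-1.66	3.1	3.99	-0.47	4.27	0.24	3.64
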