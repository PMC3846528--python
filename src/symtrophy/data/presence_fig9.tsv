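# EC-by-organism presence matrix transcribed from the study's compartment
# annotations (pathway figures and Results text). 3.1.3.15c = candidate
# IMPase-family histidinol-phosphate phosphatase of the endosymbionts.
ec	A_deanei	A_desouzai	S_culicis	S_oncopelti	S_galati	K_crithidii	K_desouzaii	K_blastocrithidii	K_oncopeltii	K_galatii	H_muscarum	C_acanthocephali
1.1.1.3	1	1	1	1	1	1	1	1	1	1	1	1
1.1.1.23	0	0	0	0	0	1	1	1	1	1	0	0
1.1.1.25	0	0	0	0	0	1	1	1	1	1	0	0
1.1.1.85	0	0	0	0	0	1	1	1	1	1	0	0
1.1.1.86	0	0	0	0	0	1	1	1	1	1	0	0
1.2.1.11	0	0	0	0	0	1	1	1	1	1	0	0
1.2.1.38	0	0	0	0	0	1	1	1	1	1	0	0
1.2.4.1	1	1	1	1	1	1	1	1	1	1	1	1
1.3.1.13	0	0	0	0	0	1	1	1	1	1	0	0
1.3.1.26	0	0	0	0	0	1	1	1	1	1	0	0
1.13.11.54	1	1	1	1	1	0	0	0	0	0	1	1
1.14.16.1	1	1	1	1	1	0	0	0	0	0	1	1
2.1.1.10	1	1	1	1	1	0	0	0	0	0	1	1
2.1.1.13	1	1	1	1	1	0	0	0	0	0	1	1
2.1.1.14	1	1	1	1	1	0	0	0	0	0	0	1
2.1.1.37	1	1	1	1	1	0	0	0	0	0	1	1
2.1.3.3	0	0	0	0	0	1	1	1	1	1	1	0
2.2.1.6	0	0	0	0	0	1	1	1	1	1	0	0
2.3.1.1	0	0	0	0	0	1	1	1	1	1	0	0
2.3.1.30	1	1	1	1	1	0	0	0	0	0	1	1
2.3.1.35	0	0	0	0	0	1	1	1	1	1	0	0
2.3.1.46	1	1	1	1	1	0	0	0	0	0	1	0
2.3.1.117	0	0	0	0	0	1	1	1	1	1	0	0
2.3.3.13	0	0	0	0	0	1	1	1	1	1	0	0
2.4.2.17	0	0	0	0	0	1	1	1	1	1	0	0
2.4.2.18	0	0	0	0	0	1	1	1	1	1	0	0
2.4.2.28	1	1	1	1	1	0	0	0	0	0	1	1
2.5.1.6	1	1	1	1	1	0	0	0	0	0	1	1
2.5.1.16	1	1	1	1	1	0	0	0	0	0	1	1
2.5.1.19	0	0	0	0	0	1	1	1	1	1	0	0
2.5.1.47	1	1	1	1	1	0	0	0	0	0	1	1
2.5.1.48	1	1	1	1	1	0	0	0	0	0	1	1
2.5.1.49	1	1	1	1	1	0	0	0	0	0	1	0
2.5.1.54	0	0	0	0	0	1	1	1	1	1	0	0
2.6.1.5	1	1	1	1	1	0	0	0	0	0	1	1
2.6.1.9	0	0	0	0	0	1	1	1	1	1	0	0
2.6.1.11	0	0	0	0	0	1	1	1	1	1	0	0
2.6.1.17	0	0	0	0	0	1	1	1	1	1	0	0
2.6.1.42	1	1	1	1	1	0	0	0	0	0	1	1
2.6.1.57	0	0	0	0	0	1	1	1	1	1	0	0
2.7.1.39	1	1	1	1	1	0	0	0	0	0	1	1
2.7.1.71	0	0	0	0	0	1	1	1	1	1	0	0
2.7.1.100	0	0	0	0	0	0	0	0	0	0	1	1
2.7.2.4	0	0	0	0	0	1	1	1	1	1	0	0
2.7.2.8	0	0	0	0	0	1	1	1	1	1	0	0
3.1.3.15c	0	0	0	0	0	1	1	1	1	1	0	0
3.1.3.77	0	0	0	0	0	0	0	0	0	0	1	1
3.2.2.9	1	1	1	1	1	0	0	0	0	0	1	1
3.2.2.16	1	1	1	1	1	0	0	0	0	0	1	1
3.3.1.1	1	1	1	1	1	0	0	0	0	0	1	1
3.5.1.14	1	1	1	1	1	0	0	0	0	0	1	1
3.5.1.16	1	1	1	1	1	0	0	0	0	0	1	1
3.5.1.18	0	0	0	0	0	1	1	1	1	1	0	0
3.5.3.1	1	1	1	1	1	0	0	0	0	0	1	1
3.5.3.11	1	1	1	1	1	0	0	0	0	0	1	1
3.5.4.19	0	0	0	0	0	1	1	1	1	1	0	0
3.6.1.31	0	0	0	0	0	1	1	1	1	1	0	0
4.1.1.17	1	1	0	0	0	0	0	0	0	0	1	1
4.1.1.19	0	0	0	0	0	1	1	1	1	1	0	0
4.1.1.20	1	1	1	1	1	1	1	1	1	1	1	1
4.1.1.48	0	0	0	0	0	1	1	1	1	1	0	0
4.1.1.50	1	1	1	1	1	0	0	0	0	0	1	1
4.1.2.5	1	1	1	1	1	0	0	0	0	0	0	1
4.1.3.-	0	0	0	0	0	1	1	1	1	1	0	0
4.1.3.27	0	0	0	0	0	1	1	1	1	1	0	0
4.2.1.9	0	0	0	0	0	1	1	1	1	1	0	0
4.2.1.10	0	0	0	0	0	1	1	1	1	1	0	0
4.2.1.19	0	0	0	0	0	1	1	1	1	1	0	0
4.2.1.20a	0	0	0	0	0	1	1	1	1	1	0	0
4.2.1.20b	1	1	1	1	1	1	1	1	1	1	1	0
4.2.1.22	1	1	1	1	1	0	0	0	0	0	1	1
4.2.1.33	0	0	0	0	0	1	1	1	1	1	0	0
4.2.1.51	0	0	0	0	0	1	1	1	1	1	0	0
4.2.1.52	0	0	0	0	0	1	1	1	1	1	0	0
4.2.1.109	1	1	1	1	1	0	0	0	0	0	1	1
4.2.3.1	1	1	1	1	1	0	0	0	0	0	1	1
4.2.3.4	0	0	0	0	0	1	1	1	1	1	0	0
4.2.3.5	0	0	0	0	0	1	1	1	1	1	0	0
4.3.1.12	1	1	1	1	1	0	0	0	0	0	0	0
4.3.1.19	1	1	1	1	1	1	1	1	1	1	1	1
4.3.2.1	1	1	1	1	1	0	0	0	0	0	1	1
4.4.1.8	1	1	1	1	1	0	0	0	0	0	1	1
5.1.1.7	0	0	0	0	0	1	1	1	1	1	1	0
5.3.1.16	0	0	0	0	0	1	1	1	1	1	0	0
5.3.1.23	1	1	1	1	1	0	0	0	0	0	1	1
5.3.1.24	0	0	0	0	0	1	1	1	1	1	0	0
5.4.99.5	0	0	0	0	0	1	1	1	1	1	0	0
6.3.4.5	1	1	1	1	1	0	0	0	0	0	1	1
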