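no	accession	f1_prime	f2_prime	enc	flags
1	AF405706	-0.79	1.32	56.41
2	X04615	-0.82	0.50	55.88
3	AB033554	-1.11	-0.90	55.78
4	AY741798	-0.82	1.31	56.17
5	AY741797	-0.82	1.15	55.82
6	AY741796	-0.72	1.23	56.62
7	AY741795	-0.75	1.26	56.59
8	AY741794	-0.73	1.26	56.61
9	AF100309	-1.02	-1.17	55.92
10	M57663	0.87	-1.05	55.48
11	AF100308	-1.16	-1.69	55.70
12	U87747	-0.38	-0.96	57.29
13	U87746	0.49	-0.27	55.71
14	AY123041	-0.69	0.77	55.94
15	AF068756	-0.48	0.70	56.39
16	AF282918	-0.84	-1.22	55.98
17	U95551	-0.99	0.62	56.36
18	GQ872210	-0.02	1.01	56.07
19	GQ161818	0.54	0.11	56.88
20	GQ161805	0.56	0.08	56.87
21	GQ161799	0.56	0.11	56.88
22	AY796032	-0.49	1.42	56.08
23	AY796031	-0.43	1.17	56.08
24	AY796030	-0.47	0.68	56.67
25	AF282917	-1.07	-1.45	55.70
26	AY233296	-0.07	1.39	55.62
27	AY23329	-0.38	1.30	56.04	truncated-accession
28	AY233294	-0.33	1.62	55.95
29	AY233293	-0.39	1.51	55.92
30	AY233291	-0.45	1.29	55.95
31	AY233290	1.42	0.25	56.75
32	AY233289	1.57	-0.49	56.66
33	AY233288	1.39	-0.33	56.84
34	AY233287	1.55	-0.14	56.82
35	AY233286	1.03	0.00	56.78
36	AY233285	1.26	-0.54	56.52
37	AY233284	1.38	-0.24	56.78
38	AY233283	1.49	-0.45	56.54
39	AY233282	1.35	-0.17	56.73
40	AY233281	1.31	-0.08	56.95
41	AY233280	1.19	0.18	56.82
42	AY233279	1.34	0.04	56.90
43	AY233278	0.86	-0.56	56.37
44	AY233277	1.55	-0.15	56.88
45	AY233276	1.38	-0.38	56.83
46	AY233275	1.87	0.03	56.79
47	AY233274	1.34	-0.30	56.60
48	AY233273	-0.49	-0.80	56.45
49	DQ448628	-1.07	-1.31	55.84
50	DQ448627	-1.07	-1.56	55.84
51	DQ448625	-1.07	-1.56	55.68
52	DQ448623	-1.07	-1.34	55.76
53	DQ448622	-0.81	-1.44	55.90
54	DQ448621	-0.94	-1.10	56.24
55	DQ448620	-1.02	-1.46	55.77	duplicate-accession
56	DQ448620	-0.90	-1.29	56.01	duplicate-accession
57	AY373432	-0.73	1.26	56.61
58	AY373430	-0.93	0.82	55.86
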