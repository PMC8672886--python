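chrom	length_mb	gc_percent	detected	expected	density	chi2	p
1	59.58	36.4	171	137.6	2.87	8.468	0.004
2	59.64	36.7	158	137.7	2.65	3.115	0.078
3	62.63	36.9	162	144.6	2.59	2.182	0.140
4	78.09	38.4	342	180.3	4.38	153.327	0.000
5	72.5	36.4	174	167.4	2.4	0.272	0.602
6	60.27	36.4	139	139.2	2.31	0.000	0.988
7	74.28	36.7	160	171.5	2.15	0.818	0.366
8	54.3	36.5	113	125.4	2.08	1.273	0.259
9	56.46	36.5	131	130.4	2.32	0.003	0.956
10	45.42	36.6	101	104.9	2.22	0.149	0.700
11	45.48	36.4	105	105	2.31	0.000	0.998
12	49.18	36.3	110	113.6	2.24	0.116	0.733
13	52.19	36.5	110	120.5	2.11	0.953	0.329
14	52.66	36.6	131	121.6	2.49	0.753	0.385
15	48.04	36.8	111	110.9	2.31	0.000	0.995
16	55.27	36.5	127	127.6	2.3	0.003	0.954
17	53.46	36.6	104	123.5	1.95	3.185	0.074
18	51.02	36.6	117	117.8	2.29	0.006	0.939
19	48.45	36.4	118	111.9	2.44	0.346	0.556
20	55.2	36.6	123	127.5	2.23	0.163	0.686
21	45.93	36.6	112	106.1	2.44	0.343	0.558
22	39.13	37	105	90.4	2.68	2.438	0.118
23	46.22	36.7	97	106.7	2.1	0.918	0.338
24	42.17	36.3	83	97.4	1.97	2.189	0.139
25	37.5	36.6	92	86.6	2.45	0.346	0.556
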