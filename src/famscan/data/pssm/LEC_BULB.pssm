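# famscan PSSM v1
id	LEC_BULB
length	50
min_score	150
alphabet	ACDEFGHIKLMNPQRSTVWY
1	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	5	-2	-2	-2	-2	-2	-2	-2	-2	-2
2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	5	-2	-2	-2	-2	-2	-2	-2	-2	-2
3	-2	-2	-2	-2	5	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2
4	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	5	-2	-2	-2
5	-2	-2	-2	-2	-2	-2	-2	5	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2
6	5	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2
7	5	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2
8	-2	-2	5	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2
9	5	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2
10	5	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2
11	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	5	-2
12	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	5	-2	-2	-2
13	-2	-2	-2	-2	-2	-2	5	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2
14	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	5	-2	-2	-2
15	-2	-2	-2	-2	5	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2
16	5	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2
17	-2	-2	-2	5	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2
18	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	5	-2	-2	-2
19	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	5	-2	-2	-2	-2	-2	-2
20	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	5	-2	-2	-2	-2
21	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	5
22	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	5
23	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	5	-2	-2	-2
24	-2	-2	-2	-2	5	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2
25	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	5	-2	-2
26	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	5	-2
27	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	5	-2	-2	-2	-2	-2	-2	-2	-2	-2
28	-2	-2	-2	-2	-2	-2	-2	-2	5	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2
29	-2	-2	-2	-2	-2	-2	5	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2
30	-2	-2	-2	-2	-2	5	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2
31	-2	-2	5	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2
32	-2	5	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2
33	-2	-2	5	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2
34	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	5
35	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	5	-2	-2
36	5	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2
37	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	5	-2	-2	-2	-2
38	-2	-2	-2	-2	5	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2
39	-2	-2	-2	-2	-2	-2	5	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2
40	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	5	-2	-2	-2	-2	-2	-2	-2	-2	-2
41	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	5
42	5	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2
43	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	5	-2	-2	-2	-2	-2	-2	-2
44	-2	-2	-2	-2	5	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2
45	-2	-2	-2	-2	-2	-2	-2	-2	-2	5	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2
46	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	5
47	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	5	-2	-2
48	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	5	-2	-2	-2	-2	-2	-2
49	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	5	-2	-2	-2	-2	-2	-2	-2
50	-2	-2	-2	5	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2
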