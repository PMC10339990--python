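# taxon: sakalavaA
# annotation NOR: second (telocentric) pair
# transcribed from the published chromosome morphometric table, Blaesodactylus sakalava clade A column (2n = 40)
# pair 5 is printed ambiguously as '6.8.1 +- 0.5' in the source table; transcribed as 6.8 (presumed typographical)
rank	rl_mean	rl_sd	ci_mean	ci_sd	morph
1	9.8	1.0	39.3	4.5	m
2	8.2	0.9	NA	NA	t
3	8.1	0.7	NA	NA	t
4	7.1	0.6	NA	NA	t
5	6.8	0.5	NA	NA	t
6	6.2	0.8	47.0	3.0	m
7	5.4	0.6	NA	NA	t
8	5.3	0.7	NA	NA	t
9	5.3	0.8	NA	NA	t
10	5.2	0.6	NA	NA	t
11	4.2	0.6	NA	NA	t
12	4.0	0.4	NA	NA	t
13	3.8	0.5	NA	NA	t
14	3.7	0.7	NA	NA	t
15	3.7	0.7	NA	NA	t
16	3.5	0.6	NA	NA	t
17	3.3	0.6	NA	NA	t
18	2.8	0.7	NA	NA	t
19	2.7	0.8	NA	NA	t
20	2.6	0.5	NA	NA	t
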