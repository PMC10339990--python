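# taxon: sakalavaB
# transcribed from the published chromosome morphometric table, Blaesodactylus sakalava clade B column (2n = 40)
rank	rl_mean	rl_sd	ci_mean	ci_sd	morph
1	9.1	0.8	43.1	3.4	m
2	8.1	0.9	NA	NA	t
3	7.8	0.6	NA	NA	t
4	6.6	0.8	NA	NA	t
5	6.4	0.6	NA	NA	t
6	6.2	0.6	46.3	3.1	m
7	6.1	0.8	NA	NA	t
8	5.7	0.6	NA	NA	t
9	5.4	0.5	NA	NA	t
10	4.9	0.4	NA	NA	t
11	4.5	0.6	NA	NA	t
12	4.1	0.7	NA	NA	t
13	3.8	0.7	NA	NA	t
14	3.6	0.9	NA	NA	t
15	3.4	0.5	NA	NA	t
16	3.1	0.8	NA	NA	t
17	3.0	0.5	NA	NA	t
18	2.8	0.4	NA	NA	t
19	2.7	0.6	NA	NA	t
20	2.6	0.7	NA	NA	t
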