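# literature haploid karyotype states for the outgroup genera, biarmed elements tallied as metacentric
# typica: Geckolepis typica, 2n = 40 with 5 biarmed pairs
# walbergii: Homopholis walbergii, 2n = 36, FN = 44 (4 biarmed pairs)
# fasciata: Homopholis fasciata, 2n = 36, FN = 40 (2 biarmed pairs)
# victori, microtuberculatus, ambonihazo: Blaesodactylus tips without karyotype data
taxon	m	sm	st	t
typica	5	0	0	15
walbergii	4	0	0	14
fasciata	2	0	0	16
victori	?	?	?	?
microtuberculatus	?	?	?	?
ambonihazo	?	?	?	?
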