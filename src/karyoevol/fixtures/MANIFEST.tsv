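file	description
antongilensis.tsv	Measured karyogram of Blaesodactylus antongilensis (2n = 40), transcribed from the published chromosome morphometric table; pair 1 CI 25.0 on the st/sm transition, pair 6 metacentric
sakalavaA.tsv	Measured karyogram of Blaesodactylus sakalava clade A (2n = 40), transcribed from the published chromosome morphometric table; pairs 1 and 6 metacentric; pair 5 RL printed ambiguously ('6.8.1 +- 0.5'), transcribed as 6.8
sakalavaB.tsv	Measured karyogram of Blaesodactylus sakalava clade B (2n = 40), transcribed from the published chromosome morphometric table; pairs 1 and 6 metacentric
boivini.tsv	Measured karyogram of Blaesodactylus boivini (2n = 42, all telocentric), transcribed from the published chromosome morphometric table
literature_states.tsv	Haploid morphology-class counts for Geckolepis typica (2n = 40, 5 biarmed) and Homopholis walbergii/fasciata (2n = 36; FN 44/40) as reported in the cytogenetic literature, plus explicit unknown rows for Blaesodactylus tips without karyotype data
tree.nwk	Rooted binary topology of the seven Blaesodactylus species-level lineages plus Geckolepis and Homopholis, redrawn from the published phylogenetic relationships (topology only; no branch lengths or support values)
specimens.tsv	The ten study specimens: taxonomic attribution, field number, origin and sex
costs.txt	Default event-cost configuration: fusion = inversion = repositioning = 1, fission = 5 (fission penalty encodes the prior that high chromosome numbers and telocentric elements are ancestral)
MANIFEST.tsv	This file
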