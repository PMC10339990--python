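# study specimens: taxonomic attribution, field number, origin and sex
species	specimen	locality	sex
B. antongilensis	GA 483	Masobe Forest, Betampona	female
B. antongilensis	GA 1049	Masobe Forest, Betampona	female
B. boivini	FGMV 3010	Montagne des Francais	female
B. sakalava clade A	FGMV 2029	Ifaty	female
B. sakalava clade A	FGMV 2030	Ifaty	male
B. sakalava clade A	FGMV 2032	Ifaty	male
B. sakalava clade B	GA 80	Isalo	male
B. sakalava clade B	GA 376	Marofandilia	juvenile
B. sakalava clade B	GA 377	Marofandilia	male
B. sakalava clade B	GA 378	Marofandilia	male
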