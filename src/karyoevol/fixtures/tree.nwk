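(((victori,(microtuberculatus,boivini)),((sakalavaA,sakalavaB),(ambonihazo,antongilensis))),(typica,(walbergii,fasciata)));
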