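mirna,gene
mir-26a-5p,Ezh2
let-7d-5p,Kdm3a
mir-199a-3p,Kdm3a
mir-199a-3p,Dnmt3a
mir-29c-3p,Dnmt3a
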