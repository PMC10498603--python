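# Harmonizome-indexed ALS risk genes among the eccDNA-DEP tandem set
Cadm2
Cdh4
Cdh13
Ctnna3
Dclk1
Gria3
Grm7
Grm8
Itpr2
Lama3
Macrod2
Plcb1
Prmd16
Ptprn2
Rbfox1
Wwox
Zbtb20
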