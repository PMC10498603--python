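# NHGRI-EBI GWAS-catalog ALS risk genes among the eccDNA-DEP tandem set
Macrod2
Itpr2
Dpp6
Lama2
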