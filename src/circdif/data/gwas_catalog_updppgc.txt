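# NHGRI-EBI GWAS-catalog ALS risk genes among the up-DPpGC set
Adamtsl1
Asic2
Camta1
Creb5
Ctnnd2
Dach1
Dpp6
Erbb4
Grid1
Itpr2
Kalrn
Kcnmb2
Lama2
Lama3
Macrod2
Mir99ahg
Opcml
Ptprn2
Trpm8
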