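# Printed subset (10 of 27) of murine recurrent-DSB-cluster (RDC) neural
# coding genes; the full 27-gene catalog must be supplied by the user.
Csmd1
Csmd3
Ntm
Cdh13
Magi1
Grik2
Rbfox1
Ctnnd2
Cadm2
Wwox
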