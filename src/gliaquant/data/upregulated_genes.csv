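gene,group,fold,common_group
Thbs1,D4,2.75,S1
Rlf,D4,2.74,"A1, C1"
Tnks2,D4,2.7,A1
Rbp1,D4,2.67,"A1, S1, C1"
Nudt21,D4,2.63,C1
Tpm2,D4,2.59,"A1, S1, C1"
Sri,D4,2.38,A1
Dab1,D4,2.35,"A1, C1"
Pmm1,D4,2.25,"A1, C1"
Sf3a3,D4,2.25,"A1, S1, C1"
Dzip1,D4,2.22,"C1, S1"
Nrg2,D4,2.19,"A1, C1"
Capn12,D4,2.17,"A1, S1, C1"
Prkar1b,D4,2.15,S1
Atp1a2,D4,2.12,A1
Hdlbp,D4,2.12,S1
Slc13a3,D4,2.12,A1
Ncapd3,D4,2.12,"A1, S1, C1"
Lima1,D4,2.07,C1
Pla2g15,D4,2.04,"A1, S1"
Ogfrl1,D4,2.03,"A1, C1"
BC024139,D4,2.02,"A1, S1, C1"
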