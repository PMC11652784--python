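gene,group,fold,common_group
Zbtb16,D4,-3.8,S1
Spcs1,D4,-2.69,"A1, S1, C1"
Igh-V7183,D4,-2.65,"A1, S1, C1"
Riok1,D4,-2.36,"A1, S1, C1"
Calr3,D4,-2.34,"A1, S1, C1"
Irf1,D4,-2.26,A1
Gna14,D4,-2.26,"A1, S1, C1"
Trip13,D4,-2.22,"A1, S1, C1"
Ndn,D4,-2.14,"A1, C1"
Plpp6,D4,-2.12,"A1, S1, C1"
Boc,D4,-2.11,"A1, S1, C1"
Ube2z,D4,-2.11,"A1, C1"
Mapre1,D4,-2.07,A1
Gm38396,D4,-2.06,C1
Cyp4a31,D4,-2.04,"A1, S1, C1"
Dcaf12l1,D4,-2.03,"A1, S1, C1"
Tfap2a,D4,-2.02,S1
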