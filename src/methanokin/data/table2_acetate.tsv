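enzyme	umol_per_mol_atp
Ack	102.0
ATPS	406
Cdh	134.4
FmdFwd	6.4
Fpo	3.96
Ftr	4.72
HdrDE	38.1
Mch	11.6
Mcr	398
Mer	1.26
MtaCBA1	3.57
MtaCBA2	5.66
MtaCBA3	141.0
Mtd	1.69
Mtr	144.4
Pta	171.0
Rnf	17.1
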