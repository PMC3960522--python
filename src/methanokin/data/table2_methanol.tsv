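enzyme	umol_per_mol_atp
Ack	37.5
ATPS	132.0
Cdh	151.0
FmdFwd	57.4
Fpo	27.8
Ftr	9.60
HdrDE	45.3
Mch	30.0
Mcr	321.8
Mer	25.5
MtaCBA1	1.97
MtaCBA2	10.78
MtaCBA3	0.20
Mtd	36.9
Mtr	112.4
Pta	36.2
Rnf	22.8
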