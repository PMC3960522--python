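enzyme	reaction	kcat_per_s	km_mM	type	primary_substrates	citation
Ack	ATP + Ac → AcP + ADP	1055	0.0713	B	ATP;Ac	Aceti1988
Ack	ADP + AcP → Ac + ATP	1260	0.098	B	ADP;AcP	Latimer1993
Pta	CoA + AcP → AcCoA + Pi	1500	0.186	B	CoA;AcP	Lundie1989
Pta	AcCoA + Pi → CoA + AcP	65.8	0.18	B	AcCoA;Pi	Lundie1989b
Cdh	AcCoA + 2 Fd_ox + H4SPT + H2O → CO + CoA + 2 Fd_red + MeH4SPT + 2 H	358.5	7.1	BC	AcCoA;H2O	Grahame1991
Cdh	CO + CoA + 2 Fd_red + MeH4SPT + 2 H → AcCoA + 2 Fd_ox + H4SPT + H2O	1130	0.9	BC	CO;MeH4SPT	Raybuck1991
MtaCBA1	MeOH + CoM + H → MeCoM + H2O	17	50	M	MeOH	Sauer1997
MtaCBA2	MeOH + CoM + H → MeCoM + H2O	15	50	M	MeOH	Sauer1997
MtaCBA3	MeOH + CoM + H → MeCoM + H2O	5	50	M	MeOH	Sauer1997
Mer	MeH4SPT + F420 + H → MethyleneH4SPT + F420H2	119.7	0.25	B	MeH4SPT;F420	Ma1991
Mer	MethyleneH4SPT + F420H2 → MeH4SPT + F420 + H	815	0.3	B	MethyleneH4SPT;F420H2	TeBrommelstroet1990
Mtd	MethyleneH4SPT + F420 + 2 H → MethenylH4SPT + F420H2	2650	0.065	B	MethyleneH4SPT;F420	Enssle1991
Mtd	MethenylH4SPT + F420H2 → MethyleneH4SPT + F420 + 2 H	408	0.065	B	MethenylH4SPT;F420H2	fit
Mch	MethenylH4SPT + H2O → FormylH4SPT + H	701	0.57	M	MethenylH4SPT	Vaupel1998
Mch	FormylH4SPT + H → MethenylH4SPT + H2O	100	0.57	M	FormylH4SPT	fit
Ftr	FormylH4SPT + Mfr → H4SPT + H + FormylMfr	1787	0.1	B	FormylH4SPT;Mfr	Enssle1991
Ftr	H4SPT + H + FormylMfr → FormylH4SPT + Mfr	262	0.1	B	H4SPT;FormylMfr	fit
FmdFwd	FormylMfr + 2 Fd_ox + H2O → CO2 + 2 Fd_red + H + Mfr	1225	0.02	BC	FormylMfr;Fd_ox	Bertram1994
FmdFwd	CO2 + 2 Fd_red + H + Mfr → FormylMfr + 2 Fd_ox + H2O	175	0.02	BC	CO2;Fd_red	fit
Mtr	H + MeH4SPT + 2 Na_c + CoM → H4SPT + 2 Na_e + MeCoM	50	3.7	B	MeH4SPT;CoM	fit
Mtr	H4SPT + 2 Na_e + MeCoM → H + MeH4SPT + 2 Na_c + CoM	50	3.7	B	MeCoM;H4SPT	fit
Mcr	MeCoM + CoB → CoBCoM + CH4	5.0	2	B	MeCoM;CoB	Ellermann1988
HdrDE	CoBCoM + MphenH2 + 2 H → CoB + CoM + Mphen + 2 He	74	0.092	B	CoBCoM;MphenH2	Murakami2001
Rnf	2 Fd_red + 3 Na_c + Mphen + 2 H → 2 Fd_ox + 3 Na_e + MphenH2	80	0.1	BC	Fd_red;Mphen	fit
Fpo	F420H2 + Mphen + H → F420 + MphenH2 + 2 He	80	0.1	B	F420H2;Mphen	fit
ATPS	ADP + Pi + 4 He → ATP + H2O + 3 H	16	0.1	BC	ADP;He	Pisa2007
CellMass	ATP → ADP + Pi + Biomass	3.4722222e-05		F	ATP	Benedict2012
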