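family	superfamily	order
BelPao	BelPao	LTR
Bel-Pao	BelPao	LTR
Pao	BelPao	LTR
BEL	BelPao	LTR
Copia	Copia	LTR
ERVK	ERVK	LTR
ERV	ERVK	LTR
Gypsy	Gypsy	LTR
CR1	CR1	LINE
I	I	LINE
Jockey	Jockey	LINE
L1	L1	LINE
L2	L2	LINE
LOA	LOA	LINE
R1	R1	LINE
R2	R2	LINE
R4	R4	LINE
RTE	RTE	LINE
hAT	hAT	TIR
Mutator	Mutator	TIR
MULE	Mutator	TIR
MuDR	Mutator	TIR
MULE-MuDR	Mutator	TIR
Novosib	Novosib	TIR
P	P	TIR
PIF/Harbinger	PIF/Harbinger	TIR
PIF-Harbinger	PIF/Harbinger	TIR
Harbinger	PIF/Harbinger	TIR
piggyBack	piggyBack	TIR
PiggyBac	piggyBack	TIR
Tc1/mariner	Tc1/mariner	TIR
TcMar	Tc1/mariner	TIR
Tc1-Mariner	Tc1/mariner	TIR
Mariner	Tc1/mariner	TIR
Transib	Transib	TIR
CMC-Transib	Transib	TIR
TIR_other	TIR other	TIR
Sola	TIR other	TIR
Academ	TIR other	TIR
Kolobok	TIR other	TIR
Ginger	TIR other	TIR
Merlin	TIR other	TIR
Zator	TIR other	TIR
Dada	TIR other	TIR
Helitron	Helitron	Helitron
Maverick	Maverick	Maverick
Polinton	Maverick	Maverick
Penelope	Penelope	Others
SINE	SINE	Others
DIRS	DIRS	Others
Others	Others	Others
Unknown	Unknown	Unknown
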