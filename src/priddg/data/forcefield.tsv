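# priddg reduced heavy-atom force field v1
# residue	atom	element	epsilon_kcal_mol	rmin_half_A	charge_e
ALA	N	N	0.170	1.85	-0.400
ALA	CA	C	0.086	2.00	0.250
ALA	C	C	0.086	2.00	0.550
ALA	O	O	0.120	1.70	-0.400
ALA	OXT	O	0.120	1.70	0.000
ALA	CB	C	0.086	2.00	0.000
ARG	N	N	0.170	1.85	-0.400
ARG	CA	C	0.086	2.00	0.250
ARG	C	C	0.086	2.00	0.550
ARG	O	O	0.120	1.70	-0.400
ARG	OXT	O	0.120	1.70	0.000
ARG	CB	C	0.086	2.00	0.000
ARG	CG	C	0.086	2.00	0.000
ARG	CD	C	0.086	2.00	0.100
ARG	NE	N	0.170	1.85	-0.200
ARG	CZ	C	0.086	2.00	0.500
ARG	NH1	N	0.170	1.85	0.300
ARG	NH2	N	0.170	1.85	0.300
ASN	N	N	0.170	1.85	-0.400
ASN	CA	C	0.086	2.00	0.250
ASN	C	C	0.086	2.00	0.550
ASN	O	O	0.120	1.70	-0.400
ASN	OXT	O	0.120	1.70	0.000
ASN	CB	C	0.086	2.00	0.300
ASN	CG	C	0.086	2.00	0.550
ASN	OD1	O	0.120	1.70	-0.550
ASN	ND2	N	0.170	1.85	-0.300
ASP	N	N	0.170	1.85	-0.400
ASP	CA	C	0.086	2.00	0.250
ASP	C	C	0.086	2.00	0.550
ASP	O	O	0.120	1.70	-0.400
ASP	OXT	O	0.120	1.70	0.000
ASP	CB	C	0.086	2.00	0.000
ASP	CG	C	0.086	2.00	0.300
ASP	OD1	O	0.120	1.70	-0.650
ASP	OD2	O	0.120	1.70	-0.650
CYS	N	N	0.170	1.85	-0.400
CYS	CA	C	0.086	2.00	0.250
CYS	C	C	0.086	2.00	0.550
CYS	O	O	0.120	1.70	-0.400
CYS	OXT	O	0.120	1.70	0.000
CYS	CB	C	0.086	2.00	0.100
CYS	SG	S	0.450	2.00	-0.100
GLN	N	N	0.170	1.85	-0.400
GLN	CA	C	0.086	2.00	0.250
GLN	C	C	0.086	2.00	0.550
GLN	O	O	0.120	1.70	-0.400
GLN	OXT	O	0.120	1.70	0.000
GLN	CB	C	0.086	2.00	0.000
GLN	CG	C	0.086	2.00	0.300
GLN	CD	C	0.086	2.00	0.550
GLN	OE1	O	0.120	1.70	-0.550
GLN	NE2	N	0.170	1.85	-0.300
GLU	N	N	0.170	1.85	-0.400
GLU	CA	C	0.086	2.00	0.250
GLU	C	C	0.086	2.00	0.550
GLU	O	O	0.120	1.70	-0.400
GLU	OXT	O	0.120	1.70	0.000
GLU	CB	C	0.086	2.00	0.000
GLU	CG	C	0.086	2.00	0.000
GLU	CD	C	0.086	2.00	0.300
GLU	OE1	O	0.120	1.70	-0.650
GLU	OE2	O	0.120	1.70	-0.650
GLY	N	N	0.170	1.85	-0.400
GLY	CA	C	0.086	2.00	0.250
GLY	C	C	0.086	2.00	0.550
GLY	O	O	0.120	1.70	-0.400
GLY	OXT	O	0.120	1.70	0.000
HIS	N	N	0.170	1.85	-0.400
HIS	CA	C	0.086	2.00	0.250
HIS	C	C	0.086	2.00	0.550
HIS	O	O	0.120	1.70	-0.400
HIS	OXT	O	0.120	1.70	0.000
HIS	CB	C	0.086	2.00	0.000
HIS	CG	C	0.086	2.00	0.150
HIS	ND1	N	0.170	1.85	-0.300
HIS	CD2	C	0.086	2.00	0.100
HIS	CE1	C	0.086	2.00	0.350
HIS	NE2	N	0.170	1.85	-0.300
ILE	N	N	0.170	1.85	-0.400
ILE	CA	C	0.086	2.00	0.250
ILE	C	C	0.086	2.00	0.550
ILE	O	O	0.120	1.70	-0.400
ILE	OXT	O	0.120	1.70	0.000
ILE	CB	C	0.086	2.00	0.000
ILE	CG1	C	0.086	2.00	0.000
ILE	CG2	C	0.086	2.00	0.000
ILE	CD1	C	0.086	2.00	0.000
LEU	N	N	0.170	1.85	-0.400
LEU	CA	C	0.086	2.00	0.250
LEU	C	C	0.086	2.00	0.550
LEU	O	O	0.120	1.70	-0.400
LEU	OXT	O	0.120	1.70	0.000
LEU	CB	C	0.086	2.00	0.000
LEU	CG	C	0.086	2.00	0.000
LEU	CD1	C	0.086	2.00	0.000
LEU	CD2	C	0.086	2.00	0.000
LYS	N	N	0.170	1.85	-0.400
LYS	CA	C	0.086	2.00	0.250
LYS	C	C	0.086	2.00	0.550
LYS	O	O	0.120	1.70	-0.400
LYS	OXT	O	0.120	1.70	0.000
LYS	CB	C	0.086	2.00	0.000
LYS	CG	C	0.086	2.00	0.000
LYS	CD	C	0.086	2.00	0.000
LYS	CE	C	0.086	2.00	0.300
LYS	NZ	N	0.170	1.85	0.700
MET	N	N	0.170	1.85	-0.400
MET	CA	C	0.086	2.00	0.250
MET	C	C	0.086	2.00	0.550
MET	O	O	0.120	1.70	-0.400
MET	OXT	O	0.120	1.70	0.000
MET	CB	C	0.086	2.00	0.000
MET	CG	C	0.086	2.00	0.060
MET	SD	S	0.450	2.00	-0.120
MET	CE	C	0.086	2.00	0.060
PHE	N	N	0.170	1.85	-0.400
PHE	CA	C	0.086	2.00	0.250
PHE	C	C	0.086	2.00	0.550
PHE	O	O	0.120	1.70	-0.400
PHE	OXT	O	0.120	1.70	0.000
PHE	CB	C	0.086	2.00	0.000
PHE	CG	C	0.086	2.00	0.000
PHE	CD1	C	0.086	2.00	0.000
PHE	CD2	C	0.086	2.00	0.000
PHE	CE1	C	0.086	2.00	0.000
PHE	CE2	C	0.086	2.00	0.000
PHE	CZ	C	0.086	2.00	0.000
PRO	N	N	0.170	1.85	-0.400
PRO	CA	C	0.086	2.00	0.250
PRO	C	C	0.086	2.00	0.550
PRO	O	O	0.120	1.70	-0.400
PRO	OXT	O	0.120	1.70	0.000
PRO	CB	C	0.086	2.00	0.000
PRO	CG	C	0.086	2.00	0.000
PRO	CD	C	0.086	2.00	0.000
SER	N	N	0.170	1.85	-0.400
SER	CA	C	0.086	2.00	0.250
SER	C	C	0.086	2.00	0.550
SER	O	O	0.120	1.70	-0.400
SER	OXT	O	0.120	1.70	0.000
SER	CB	C	0.086	2.00	0.250
SER	OG	O	0.120	1.70	-0.250
THR	N	N	0.170	1.85	-0.400
THR	CA	C	0.086	2.00	0.250
THR	C	C	0.086	2.00	0.550
THR	O	O	0.120	1.70	-0.400
THR	OXT	O	0.120	1.70	0.000
THR	CB	C	0.086	2.00	0.250
THR	OG1	O	0.120	1.70	-0.250
THR	CG2	C	0.086	2.00	0.000
TRP	N	N	0.170	1.85	-0.400
TRP	CA	C	0.086	2.00	0.250
TRP	C	C	0.086	2.00	0.550
TRP	O	O	0.120	1.70	-0.400
TRP	OXT	O	0.120	1.70	0.000
TRP	CB	C	0.086	2.00	0.000
TRP	CG	C	0.086	2.00	0.000
TRP	CD1	C	0.086	2.00	0.150
TRP	NE1	N	0.170	1.85	-0.300
TRP	CE2	C	0.086	2.00	0.150
TRP	CD2	C	0.086	2.00	0.000
TRP	CE3	C	0.086	2.00	0.000
TRP	CZ2	C	0.086	2.00	0.000
TRP	CZ3	C	0.086	2.00	0.000
TRP	CH2	C	0.086	2.00	0.000
TYR	N	N	0.170	1.85	-0.400
TYR	CA	C	0.086	2.00	0.250
TYR	C	C	0.086	2.00	0.550
TYR	O	O	0.120	1.70	-0.400
TYR	OXT	O	0.120	1.70	0.000
TYR	CB	C	0.086	2.00	0.000
TYR	CG	C	0.086	2.00	0.000
TYR	CD1	C	0.086	2.00	0.000
TYR	CD2	C	0.086	2.00	0.000
TYR	CE1	C	0.086	2.00	0.000
TYR	CE2	C	0.086	2.00	0.000
TYR	CZ	C	0.086	2.00	0.250
TYR	OH	O	0.120	1.70	-0.250
VAL	N	N	0.170	1.85	-0.400
VAL	CA	C	0.086	2.00	0.250
VAL	C	C	0.086	2.00	0.550
VAL	O	O	0.120	1.70	-0.400
VAL	OXT	O	0.120	1.70	0.000
VAL	CB	C	0.086	2.00	0.000
VAL	CG1	C	0.086	2.00	0.000
VAL	CG2	C	0.086	2.00	0.000
A	P	P	0.585	2.15	1.200
A	OP1	O	0.120	1.70	-0.800
A	OP2	O	0.120	1.70	-0.800
A	OP3	O	0.120	1.70	0.000
A	O5'	O	0.120	1.70	-0.300
A	O3'	O	0.120	1.70	-0.300
A	C1'	C	0.086	2.00	0.100
A	O4'	O	0.120	1.70	-0.300
A	C4'	C	0.086	2.00	0.100
A	C2'	C	0.086	2.00	0.050
A	O2'	O	0.120	1.70	-0.350
A	C3'	C	0.086	2.00	0.200
A	C5'	C	0.086	2.00	0.200
A	N9	N	0.170	1.85	0.150
A	C8	C	0.086	2.00	0.250
A	N7	N	0.170	1.85	-0.300
A	C5	C	0.086	2.00	0.000
A	C6	C	0.086	2.00	0.350
A	N6	N	0.170	1.85	-0.300
A	N1	N	0.170	1.85	-0.300
A	C2	C	0.086	2.00	0.200
A	N3	N	0.170	1.85	-0.250
A	C4	C	0.086	2.00	0.200
C	P	P	0.585	2.15	1.200
C	OP1	O	0.120	1.70	-0.800
C	OP2	O	0.120	1.70	-0.800
C	OP3	O	0.120	1.70	0.000
C	O5'	O	0.120	1.70	-0.300
C	O3'	O	0.120	1.70	-0.300
C	C1'	C	0.086	2.00	0.100
C	O4'	O	0.120	1.70	-0.300
C	C4'	C	0.086	2.00	0.100
C	C2'	C	0.086	2.00	0.050
C	O2'	O	0.120	1.70	-0.350
C	C3'	C	0.086	2.00	0.200
C	C5'	C	0.086	2.00	0.200
C	N1	N	0.170	1.85	0.150
C	C2	C	0.086	2.00	0.500
C	O2	O	0.120	1.70	-0.500
C	N3	N	0.170	1.85	-0.350
C	C4	C	0.086	2.00	0.400
C	N4	N	0.170	1.85	-0.300
C	C5	C	0.086	2.00	-0.100
C	C6	C	0.086	2.00	0.200
G	P	P	0.585	2.15	1.200
G	OP1	O	0.120	1.70	-0.800
G	OP2	O	0.120	1.70	-0.800
G	OP3	O	0.120	1.70	0.000
G	O5'	O	0.120	1.70	-0.300
G	O3'	O	0.120	1.70	-0.300
G	C1'	C	0.086	2.00	0.100
G	O4'	O	0.120	1.70	-0.300
G	C4'	C	0.086	2.00	0.100
G	C2'	C	0.086	2.00	0.050
G	O2'	O	0.120	1.70	-0.350
G	C3'	C	0.086	2.00	0.200
G	C5'	C	0.086	2.00	0.200
G	N9	N	0.170	1.85	0.150
G	C8	C	0.086	2.00	0.250
G	N7	N	0.170	1.85	-0.300
G	C5	C	0.086	2.00	0.000
G	C6	C	0.086	2.00	0.500
G	O6	O	0.120	1.70	-0.500
G	N1	N	0.170	1.85	-0.300
G	C2	C	0.086	2.00	0.400
G	N2	N	0.170	1.85	-0.300
G	N3	N	0.170	1.85	-0.300
G	C4	C	0.086	2.00	0.400
U	P	P	0.585	2.15	1.200
U	OP1	O	0.120	1.70	-0.800
U	OP2	O	0.120	1.70	-0.800
U	OP3	O	0.120	1.70	0.000
U	O5'	O	0.120	1.70	-0.300
U	O3'	O	0.120	1.70	-0.300
U	C1'	C	0.086	2.00	0.100
U	O4'	O	0.120	1.70	-0.300
U	C4'	C	0.086	2.00	0.100
U	C2'	C	0.086	2.00	0.050
U	O2'	O	0.120	1.70	-0.350
U	C3'	C	0.086	2.00	0.200
U	C5'	C	0.086	2.00	0.200
U	N1	N	0.170	1.85	0.150
U	C2	C	0.086	2.00	0.500
U	O2	O	0.120	1.70	-0.500
U	N3	N	0.170	1.85	-0.250
U	C4	C	0.086	2.00	0.450
U	O4	O	0.120	1.70	-0.450
U	C5	C	0.086	2.00	-0.100
U	C6	C	0.086	2.00	0.200
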