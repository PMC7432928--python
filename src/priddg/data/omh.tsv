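# Optimal matching hydrophobicity scale v1
# aa	omh
A	-0.400
C	0.170
D	-1.310
E	-1.220
F	1.920
G	-0.670
H	-0.640
I	1.250
K	-0.670
L	1.220
M	1.020
N	-0.920
P	-0.490
Q	-0.910
R	-0.590
S	-0.550
T	-0.280
V	0.910
W	0.500
Y	1.670
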