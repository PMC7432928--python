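# Heavy-atom vdW radii for SASA, A v1
# element	radius
C	1.87
N	1.65
O	1.40
S	1.85
P	1.90
DEFAULT	1.80
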