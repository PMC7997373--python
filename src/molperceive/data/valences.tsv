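# Allowed total valences per element (comma-separated, ascending).
# Used as the target set for valence-constrained bond-order filtering.
#symbol	valences
H	1
C	4
N	3
O	2
F	1
Na	1
Mg	2
P	3,5
S	2,4,6
Cl	1
K	1
Ca	2
Br	1
I	1
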