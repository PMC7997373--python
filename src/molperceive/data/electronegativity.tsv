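# Electronegativities on the Pauling scale (dimensionless).
# The scale is swappable at run time (ElementTable(chi_overrides=...));
# the bond-length correction is linear in the difference, so replacing
# the table is a pure data change.
#symbol	chi
H	2.20
C	2.55
N	3.04
O	3.44
F	3.98
Na	0.93
Mg	1.31
P	2.19
S	2.58
Cl	3.16
K	0.82
Ca	1.00
Br	2.96
I	2.66
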