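# UFF nonbonded parameters (Rappe, Casewit, Colwell, Goddard, Skiff 1992):
# x = van der Waals distance (Angstrom, the 12-6 minimum), d = well depth
# (kcal/mol). Combined by geometric means.
#symbol	x	d
H	2.886	0.044
C	3.851	0.105
N	3.660	0.069
O	3.500	0.060
F	3.364	0.050
Na	2.983	0.030
Mg	3.021	0.111
P	4.147	0.305
S	4.035	0.274
Cl	3.947	0.227
K	3.812	0.035
Ca	3.399	0.238
Br	4.189	0.251
I	4.009	0.339
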