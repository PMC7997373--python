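# Charge-equilibration parameters (Rappe-Goddard 1991), element level:
# chi0 = neutral-atom electronegativity (eV), hardness = idempotential
# J_ii (eV / e^2). The table is swappable (ElementTable(qeq_overrides=...)).
#symbol	chi0	hardness
H	4.528	13.890
C	5.343	10.126
N	6.899	11.760
O	8.741	13.364
F	10.874	14.948
Na	2.843	4.592
Mg	3.951	7.386
P	5.463	8.000
S	6.928	8.972
Cl	8.564	9.892
K	2.421	3.840
Ca	3.231	5.760
Br	7.790	8.850
I	6.822	7.524
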