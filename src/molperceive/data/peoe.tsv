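# Gasteiger-Marsili PEOE electronegativity polynomial coefficients:
#   chi(q) = a + b*q + c*q^2   (eV-like scale of the original fit).
# hyb column selects the coefficient set by hybridization state;
# '*' matches any state (elements whose parameters are state-independent).
#symbol	hyb	a	b	c
H	*	7.17	6.24	-0.56
C	sp3	7.98	9.18	1.88
C	sp2	8.79	9.32	1.51
C	sp	10.39	9.45	0.73
N	sp3	11.54	10.82	1.36
N	sp2	12.87	11.15	0.85
N	sp	15.68	11.70	-0.27
O	sp3	14.18	12.92	1.39
O	sp2	17.07	13.79	0.47
F	*	14.66	13.85	2.31
Cl	*	11.00	9.69	1.35
Br	*	10.08	8.47	1.16
I	*	9.90	7.96	0.96
S	*	10.14	9.13	1.38
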