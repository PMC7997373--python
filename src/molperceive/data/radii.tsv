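# Covalent radii in Angstrom.
# r_cov: single-bond covalent radius (Cordero et al. 2008), used for
#   equilibrium bond lengths and hydrogen cap placement.
# r_pyykko_s/d/t: Pyykko self-consistent single/double/triple-bond radii
#   (2009 tabulation); '-' marks an absent value. Entries breaking the
#   monotonic ordering r_t < r_d < r_s (Na double, S and Br triple) are
#   omitted so the log-linear bond-order fit stays monotone.
# max_coordination: hard cap on covalent neighbours used by bond pruning.
#symbol	Z	r_cov	r_pyykko_s	r_pyykko_d	r_pyykko_t	max_coordination
H	1	0.31	0.32	-	-	1
C	6	0.76	0.75	0.67	0.60	4
N	7	0.71	0.71	0.60	0.54	4
O	8	0.66	0.63	0.57	0.53	3
F	9	0.57	0.64	0.59	0.53	1
Na	11	1.66	1.55	-	-	1
Mg	12	1.41	1.39	1.32	1.27	2
P	15	1.07	1.11	1.02	0.94	6
S	16	1.05	1.03	0.94	-	6
Cl	17	1.02	0.99	0.95	0.93	1
K	19	2.03	1.96	1.93	-	1
Ca	20	1.76	1.71	1.47	1.33	2
Br	35	1.20	1.14	1.09	-	1
I	53	1.39	1.33	1.29	1.25	1
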