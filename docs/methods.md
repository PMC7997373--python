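# Methods

This note records the modelling choices behind each perception stage:
what is assumed, which parameters matter, what the generated reference
molecules do and do not exercise, and where the design was genuinely open.

## Continuous bond perception

The strength of a candidate bond is a plateau-Gaussian in the distance:
1 on [0, r_e], `exp(−(r−r_e)²/2σ_r²)` beyond. The piecewise form is chosen
so the score is exactly 1 anywhere at or below the reference length and is
still C¹ at the joint (both one-sided derivatives vanish at r_e); a plain
Gaussian centred at r_e would instead penalize compressed bonds, which a
presence score should not.

The reference length is the Schomaker–Stevenson corrected radii sum
`r_e = R_cov(a) + R_cov(b) − c_en·|Δχ|`, with Cordero covalent radii and
Pauling electronegativities by default and `c_en = 0.09 Å` per
electronegativity unit. The electronegativity term is what keeps very
polar contacts — the classic failure case being K⁺ coordinated by
carbonyl oxygens — from being perceived as covalent: it shortens r_e for
such pairs enough that ionic distances fall into the decaying tail. Both
the scale and `c_en` are swappable (`ElementTable(chi_overrides=...)`,
config) because the correction is linear in the tabulated values.
`r_e` is floored at 0.4·(radii sum) purely as degenerate-input protection;
no real element pair reaches the floor.

Three constants anchor the model and are deliberately the same number:
minimum distance 0.4 Å (below which a pair is logged as a suspected clash
and skipped), tolerance 0.4 Å, and acceptance threshold 0.4. σ_r is not an
independent parameter: it is calibrated so that strength(r_e + tolerance)
= threshold, i.e. `σ_r = tolerance/√(−2 ln threshold)`. This ties the
Gaussian width to the two printed cut-offs and makes the acceptance rule
"distance within tolerance" and "strength above threshold" coincide.

After assignment, any atom whose covalent bond count exceeds its maximum
coordination (a per-element table: H 1, C 4, N 4, O 3, alkali metals 1, …)
loses incident bonds weakest-first; ties break toward the longer bond and
then the smaller index pair, so the result is independent of atom order.

Candidate pairs come from a KD-tree with cut-off `2·max(R_cov) +
tolerance`, which bounds every possible r_e + tolerance; a test asserts
exact agreement with an all-pairs scan on random packings.

Hydrogen bonds reuse the radial profile on the donor–acceptor heavy-atom
distance (per-pair r_e: O–O 2.9 Å, O–N 3.0 Å, N–N 3.1 Å) times an angular
plateau-Gaussian in the donor–H–acceptor angle centred at 180°, calibrated
so B(120°) = 0.4. N and O act as donors and acceptors; C–H groups do not.
The donor–acceptor (rather than H–acceptor) distance convention and the
numeric defaults are this package's choices — they reproduce the textbook
water-dimer geometry (O···O = 2.9 Å, linear, strength 1) and are all in
config. Hydrogen-bond perception never alters covalent topology.

## Ring perception

Blocks are the cyclic biconnected components of the covalent graph
(equivalently: strip degree-≤1 vertices, split at articulation points,
discard bridges); networkx supplies the biconnected decomposition. Within
each block, Horton's algorithm builds one candidate cycle per (vertex v,
edge (x, y)) from BFS shortest paths SP(v,x) + (x,y) + SP(y,v), keeps the
simple ones, sorts by length, and greedily accepts cycles that are
linearly independent over GF(2) (incremental bit-set elimination) until
|E| − |V| + 1 have been found. By Horton's theorem the result is a
minimum cycle basis. An MCB is not unique, so every tie is broken
deterministically: BFS visits neighbours in ascending index, and equal-
length candidates order by their sorted edge sets. Tests verify, on random
graphs, that the basis weight equals an exhaustive oracle (greedy GF(2)
selection over *all* simple cycles) and that per-block and whole-graph
runs return identical rings — block partitioning is purely a speed-up.

A configurable ring-size cap (default 20) discards pathological candidate
cycles; an incomplete basis is logged rather than silently accepted.

Planarity: the mean of |dihedral| over all consecutive atom quadruples
around the cycle, compared to 7.5° for 4–5-rings and 15° for rings of six
or more atoms; 3-rings are planar by construction (three points always
are — the alternative of skipping them would silently drop cyclopropane
rings from the sp² override, which seems worse).

## Hybridization

Precedence: configured transition elements → `metal` (an honest sentinel;
no angle rule is attempted for them); planar-ring members → sp²; atoms
with ≥ 2 bonds → mean-angle heuristic; terminal atoms → bond-length rules
for O/N/C, `unknown` otherwise.

The angle cut-offs 155° and 115° sit midway between the ideal 180°/120°
and 120°/109.5° geometries and are configurable. Terminal O is sp² when
its bond is within 0.1 Å of the Pyykkö double-bond radii sum (carbonyls),
else sp³; terminal N and C first try the triple-bond sum (nitriles,
terminal alkynes → sp), then the double-bond test. The 0.1 Å slack absorbs
typical geometry noise without misclassifying single bonds, whose lengths
sit ≈ 0.15–0.2 Å above the double-bond sums for C/N/O.

## Charges

Gasteiger PEOE uses the original quadratic electronegativity coefficients
per hybridization state (shipped in `data/peoe.tsv`); iteration k
transfers `(χ_j − χ_i)/χ⁺ · (1/2)^k` across each bond, with the donor's
cation electronegativity χ⁺ = χ(+1) (20.02 for H) as normalizer. Charges
are seeded with the net charge spread uniformly, so any requested total is
conserved exactly at every iteration. Six iterations (default) leave
changes below ~10⁻²; the cross-check against an independent PEOE
implementation (RDKit) at 12 iterations agrees to < 10⁻⁴ e on the shared
parameter set. Elements without coefficients (e.g. alkali metals) raise a
parameterization error instead of guessing.

QEq minimizes `E(q) = Σχ⁰q + ½ qᵀJq` under Σq = Q, solved as one KKT
linear system; the residual is checked to ≤ 10⁻¹⁰ relative. Element-level
Rappé–Goddard parameters (χ⁰, idempotential J_ii in eV) are used — a
force-field-specific atom-typing layer is out of scope here, and the
parameter table is swappable. The off-diagonal interaction defaults to
the shielded form `14.4/√(r² + r₀²)` eV with `r₀ = 2·14.4/(J_ii+J_jj)` Å,
which tends to the mean idempotential at r → 0 instead of diverging; a
plain `14.4/r` is available by config. Note the known QEq behaviour that
an isolated ion pair dissociates to *fractional* charges: the transferred
charge `Δχ/(J_ii+J_jj−2J_ij)` decreases monotonically with separation.

PEOE sees only topology, QEq only geometry; they share the same
`MolecularSystem` and both conserve the total charge to 10⁻⁸ or better.

## Bond orders

Per element, the Pyykkö single/double/triple radii are fitted with
`r(BO) = a − b·ln BO`. This log-linear (Pauling-type) form is the one
exponential law whose two-atom sum inverts in closed form,
`BO(d) = exp((a_A+a_B−d)/(b_A+b_B))`; a per-atom `a·e^(−b·BO)` would not.
Elements with two radii are interpolated exactly; with one (H, Na), the
slope falls back to the radii-weighted mean over all fitted elements.
Three tabulated entries (S and Br triple, Na double radii) are *larger*
than the preceding radius and are excluded so every curve is strictly
decreasing. Raw orders are clamped below at 0.1 and flagged above 4.

Filtering solves `min ‖x − x₀‖² s.t. A·x = v` through the KKT normal
equations (`A·Aᵀ λ = v − A·x₀`, minimum-norm λ via least squares for
rank-deficient constraint sets). Constrained atoms: H fixed at valence 1;
multi-valent elements (S: 2/4/6, P: 3/5) take the allowed valence nearest
their raw sum, ties downward; terminal non-hydrogens, metal-labelled atoms
and atoms of unknown hybridization are exempt by default (their valence is
genuinely ambiguous, and constraining ions produces infeasibility).
Negative projected orders are clamped to zero and the projection re-solved
once with those bonds fixed — chemical orders are non-negative, and at
molecular scale a full active-set loop is not needed (the single re-solve
is verified against an inequality-aware oracle on random instances).
If constraints cannot be met within 10⁻⁶ the raw orders are returned with
`feasible = False` and a per-atom diagnostic.

Bond strength and bond order are decoupled fields: assigning orders never
changes the perceived bond set.

## Biaryl bridges and fragments

A bridge is a covalent bond joining atoms of two *distinct planar* rings
that is not itself an edge of any ring. The not-a-ring-edge clause is what
makes fused systems (naphthalene) bridge-free while reporting both
celecoxib bridges; couples involving a non-planar ring are logged, not
returned. Fragments keep the union of the two graph-distance balls (default
depth 4) around the bridge atoms; each severed bond K→removed becomes a
hydrogen cap on the same direction at `R_cov(K) + R_cov(H)`. The V2
(2-fold torsion) coefficient per bridge comes from a pluggable provider:
either an external table (values passed through verbatim) or a built-in
linear |Δχ| map whose output is explicitly labelled uncalibrated — the
published electronegativity→V2 regression coefficients are not available
here, so the default exists to keep the pipeline runnable, not to be
trusted numerically.

## Grids and torsion surfaces

ESP grids evaluate `V(p) = k Σ q_i/|p − r_i|` on a regular box
(`e/Å`, k = 1, or atomic units by config); voxels within 10⁻⁶ Å of an atom
are evaluated at that floor and counted in the log. Cube export follows
the Gaussian convention exactly (header and positions in Bohr, factor
0.52917721067 Å/Bohr, z-fastest values, six per line) and is round-trip
tested against an independent parse.

Torsion rotation is rigid: removing the central bond must bipartition the
graph (ring bonds raise a non-rotatable error) and the side holding the
fourth atom turns about the bond axis by Rodrigues rotation, preserving
every intra-side distance to 10⁻⁹ Å. Scans rotate both torsions from the
*same* reference conformation at every grid point, so the surface is
independent of evaluation order and 360°-periodic by construction.
Energies are UFF 12-6 vdW (geometric-mean combination, original UFF
parameters) + Coulomb (332.0637 kcal·Å/mol·e²) + `V2/2·(1 − cos 2φ)` per
bridge, excluding 1-2 and 1-3 pairs; 1-4 pairs enter unscaled, the UFF
convention. A positive V2 penalizes the perpendicular geometry; sign and
form are configurable since downstream conventions differ. Conformations
with any non-bonded contact below 0.5 Å get a finite sentinel energy
(10⁶ kcal/mol) and a flag, so divergent points survive file export.

## Reference molecules and their limits

All fixtures are generated from ideal geometries (bond lengths 0.96/1.09/
1.39/1.54 Å, ideal angles); celecoxib is a frozen MMFF94-relaxed conformer
embedded as text. They exercise exact symmetries (equal charges, order
1.5, strength 1 at r_e) that real, noisy coordinates will not reproduce
exactly: on experimental structures, strengths fall below 1, aromatic
orders spread around 1.5, and planarity flags depend on the refinement.
Passing these tests therefore demonstrates correctness of the algorithms
and calibrations, not robustness to coordinate noise; the continuous
formulation (tolerance, thresholds) is the mechanism intended to supply
that robustness, and the clash/flag/log channels are the visibility into
borderline cases. Crystallographic structures without hydrogens are
perceived heavy-atom-only (no hydrogen bonds); no protonation is invented.

Problem sizes used throughout the tests and the acceptance script —
molecules up to 40 atoms, 200 random graphs of ≤ 12 vertices for the ring
oracle, 100 random projection instances, 45°-step scans — were chosen as
the smallest sizes at which every code path and symmetry class is
exercised; all stages scale to protein-sized inputs through the KD-tree
neighbour search and per-block ring perception.

## Known limitations

- No halogen bonds, π-stacking, metal-coordination typing, or disulfide
  special-casing in perception; transition metals receive only the
  `metal` sentinel.
- PEOE parameters cover H, C, N, O, S and halogens; others fail loudly.
- QEq uses element-level parameters; no atom-type refinement.
- Valence filtering clamps negative orders with a single re-solve rather
  than a full active-set iteration.
- The built-in V2 provider is uncalibrated by design.
- No geometry optimization; scan surfaces are rigid-rotation only.
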