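# molperceive

Continuous molecular perception: given nothing but element symbols and
Cartesian coordinates, infer a molecule's covalent and hydrogen bonds,
rings, hybridization states, partial charges, and bond orders — and use
them for biaryl torsion parameterization hand-offs and potential-energy /
electrostatic-potential grids.

The package is aimed at the first steps of molecular-modelling studies
(building topological models for visualization or as force-field input)
where only a geometry is available: an XYZ file, a PDB entry, a MOL v3000
export.

## The models

**Bond perception is continuous.** A candidate bond between atoms *a*, *b*
at distance *r* gets a strength in (0, 1]:

    A(r) = 1                              for r ≤ r_e
    A(r) = exp(−(r − r_e)² / 2σ_r²)       for r > r_e

with the equilibrium length from the Schomaker–Stevenson
electronegativity-corrected radii sum, r_e = R_cov(a) + R_cov(b) −
c·|χ_a − χ_b| (c = 0.09 Å by default, Pauling χ). The width σ_r is fixed
by requiring A(r_e + tolerance) = threshold, with tolerance = 0.4 Å and
threshold = 0.4; pairs closer than 0.4 Å are treated as suspected clashes.
Bonds above threshold are kept, then any atom exceeding its allowed
coordination loses its weakest bonds. Hydrogen bonds (N/O donors and
acceptors) multiply the same radial profile on the donor–acceptor distance
by an angular factor B(θ) of identical form centred at θ = 180°.

**Rings** come from a minimum cycle basis: the covalent graph is split
into cyclic blocks (biconnected components), and Horton's algorithm —
shortest-path candidate cycles, greedily accepted while independent over
the GF(2) edge space — runs per block.

**Hybridization** is a precedence of rules: planar-ring members are sp²
(mean intra-ring torsion < 7.5° for 4–5-rings, < 15° for larger);
multi-bonded atoms use mean bond angles (≥ 155° sp, ≥ 115° sp², else sp³);
terminal O/N/C are classified by comparing their bond length against
Pyykkö double/triple radii sums; other terminal atoms stay `unknown`.

**Charges**: Gasteiger PEOE (topology-only iterative electronegativity
equalization) and QEq charge equilibration (geometry-only constrained
linear solve with a shielded Coulomb interaction).

**Bond orders** are continuous: each element's Pyykkö single/double/triple
radii are fitted with r(BO) = a − b·ln BO, which inverts in closed form
for a bond, BO(d) = exp((a_A + a_B − d)/(b_A + b_B)). Raw orders are then
projected onto the space where every constrained atom's incident orders
sum to an allowed valence (an equality-constrained least-squares /
Lagrange-multiplier problem), giving, e.g., exactly 1.5 for every aromatic
C–C bond of benzene.

**Biaryls**: bonds joining two distinct planar rings (and not lying in any
ring) are bridge bonds; the surrounding geometry is cut at a graph-distance
radius with hydrogen caps placed along the severed bond directions at the
sum of covalent radii, and exported as MOL2 + bridge-serial files for
torsion-parameter tools (HTEQ-style). Rigid two-torsion energy surfaces
(UFF 12-6 vdW + Coulomb + per-bridge 2-fold torsion term) and Coulomb ESP
voxel grids (Gaussian cube export) support interactive exploration.

## Worked example

```
$ python - <<'EOF'
from molperceive.fixtures import benzene
from molperceive.bond_perception import perceive_covalent_bonds
from molperceive.ring_perception import perceive_rings
from molperceive.hybridization import assign_hybridization
from molperceive.bond_orders import assign_bond_orders

mol = benzene()
perceive_covalent_bonds(mol)
rings = perceive_rings(mol)
labels = assign_hybridization(mol, rings)
orders = assign_bond_orders(mol)
print("bonds:", len(mol.bonds("covalent")))
print("ring sizes:", [r.size for r in rings], "planar:", [r.planar for r in rings])
print("carbon labels:", labels[:6])
print("C-C orders:", [round(b.order, 3) for b in mol.bonds("covalent")
                      if mol.atoms[b.i].symbol == mol.atoms[b.j].symbol == "C"])
EOF
bonds: 12
ring sizes: [6] planar: [True]
carbon labels: ['sp2', 'sp2', 'sp2', 'sp2', 'sp2', 'sp2']
C-C orders: [1.5, 1.5, 1.5, 1.5, 1.5, 1.5]
```

The 12 bonds are the six aromatic C–C plus six C–H; the single ring is
planar, so its carbons are forced sp²; and valence filtering turns the
distance-based raw orders into the textbook aromatic 1.5 (each carbon's
orders sum exactly to 4, each hydrogen's to 1).

The same stages are available from the shell:

```
molperceive pipeline water.xyz          # one JSON document, all stages
molperceive bonds file.pdb --hbonds     # TSV: serial_i serial_j kind length strength
molperceive rings file.mol
molperceive charges file.xyz --method qeq
molperceive bondorders file.xyz
molperceive biaryl file.mol --depth 4 --outdir out/
molperceive esp file.xyz --spacing 0.5 -o esp.cube
molperceive scan file.xyz --t1 3,1,2,6 --t2 6,2,1,3 --step 10
```

## Layout

- `src/molperceive/chem_data.py` — element tables (TSV files under
  `src/molperceive/data/`, documented column by column in place)
- `mol_io.py` — XYZ / PDB / MOL v3000 readers; multi-model XYZ, MOL2,
  Gaussian cube, bridge-serial writers
- `bond_perception.py`, `ring_perception.py`, `hybridization.py`,
  `charges.py`, `bond_orders.py`, `biaryl.py`, `grids.py` — the stages
- `pipeline.py`, `cli.py` — end-to-end driver and `molperceive` console
  command
- `fixtures.py` — generated reference molecules
- `docs/methods.md` — modelling assumptions, parameter choices, and
  known limitations
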