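import numpy as np
import pytest

from molperceive import fixtures as fx
from molperceive.biaryl import find_bridge_bonds
from molperceive.bond_perception import perceive_covalent_bonds
from molperceive.charges import ChargeSet, qeq_charges
from molperceive.chem_data import get_element
from molperceive.core import MolecularSystem
from molperceive.grids import (
    NonRotatableError,
    conformer_energy,
    esp_grid,
    rotate_torsion,
    torsion_scan,
)
from molperceive.ring_perception import dihedral_angle, perceive_rings


def _point_charge_system(symbols, coords, charges):
    system = MolecularSystem.from_symbols_coords(symbols, coords)
    return system, ChargeSet("qeq", np.array(charges, dtype=float),
                             float(np.sum(charges)), 0.0)


# ------------------------------------------------- ESP

def test_esp_coulomb_closed_form():
    system, cs = _point_charge_system(["H"], [[0.0, 0.0, 0.0]], [1.0])
    grid = esp_grid(system, cs, origin=(1.0, 0.0, 0.0), extents=(0.5, 0.5, 0.5),
                    spacing=1.0)
    assert grid.values[0, 0, 0] == pytest.approx(1.0, abs=1e-12)


def test_esp_linear_in_charges():
    system, cs = _point_charge_system(["O", "H"], [[0, 0, 0], [1, 0, 0]], [-0.8, 0.8])
    grid1 = esp_grid(system, cs, (-2, -2, -2), (4, 4, 4), 1.0)
    cs2 = ChargeSet("qeq", 2 * cs.charges, 0.0, 0.0)
    grid2 = esp_grid(system, cs2, (-2, -2, -2), (4, 4, 4), 1.0)
    assert np.allclose(grid2.values, 2 * grid1.values, atol=1e-12)


def test_esp_midpoint_of_opposite_charges_cancels():
    system, cs = _point_charge_system(["H", "H"], [[-1, 0, 0], [1, 0, 0]], [1.0, -1.0])
    grid = esp_grid(system, cs, (0.0, 0.0, 0.0), (0.5, 0.5, 0.5), 1.0)
    assert grid.values[0, 0, 0] == pytest.approx(0.0, abs=1e-12)


def test_esp_superposition_over_charge_sets():
    system, cs_a = _point_charge_system(["O", "H"], [[0, 0, 0], [1, 0, 0]], [-0.4, 0.4])
    cs_b = ChargeSet("qeq", np.array([0.3, -0.3]), 0.0, 0.0)
    cs_sum = ChargeSet("qeq", cs_a.charges + cs_b.charges, 0.0, 0.0)
    box = ((-3, -3, -3), (6, 6, 6), 1.5)
    ga = esp_grid(system, cs_a, *box)
    gb = esp_grid(system, cs_b, *box)
    gsum = esp_grid(system, cs_sum, *box)
    assert np.allclose(ga.values + gb.values, gsum.values, atol=1e-12)


def test_esp_rejects_empty_box():
    system, cs = _point_charge_system(["H"], [[0, 0, 0]], [1.0])
    with pytest.raises(ValueError, match="box"):
        esp_grid(system, cs, (0, 0, 0), (0.0, 1.0, 1.0), 0.5)


# ------------------------------------------------- torsion rotation

def _ethane_torsion(system):
    # H–C–C–H quadruple
    return (2, 0, 1, 5)


def test_rotation_to_current_angle_is_identity():
    system = fx.ethane()
    perceive_covalent_bonds(system)
    t = _ethane_torsion(system)
    current = dihedral_angle(*(system.coords()[k] for k in t))
    rotated = rotate_torsion(system, t, current)
    assert np.abs(rotated.coords() - system.coords()).max() < 1e-9


def test_rotation_by_full_turn_is_identity():
    system = fx.ethane()
    perceive_covalent_bonds(system)
    t = _ethane_torsion(system)
    current = dihedral_angle(*(system.coords()[k] for k in t))
    rotated = rotate_torsion(system, t, current + 360.0)
    assert np.abs(rotated.coords() - system.coords()).max() < 1e-9


def test_rotation_sets_requested_dihedral():
    system = fx.ethane()
    perceive_covalent_bonds(system)
    t = _ethane_torsion(system)
    for target in (0.0, 60.0, -120.0, 173.25):
        rotated = rotate_torsion(system, t, target)
        got = dihedral_angle(*(rotated.coords()[k] for k in t))
        assert abs((got - target + 180) % 360 - 180) < 1e-6


def test_eclipsing_shrinks_cross_distances_preserves_side_geometry():
    staggered = fx.ethane()
    perceive_covalent_bonds(staggered)
    t = _ethane_torsion(staggered)
    eclipsed = rotate_torsion(staggered, t, 0.0)
    cs, ce = staggered.coords(), eclipsed.coords()
    # bond lengths unchanged
    for b in staggered.bonds("covalent"):
        assert np.linalg.norm(ce[b.i] - ce[b.j]) == pytest.approx(
            np.linalg.norm(cs[b.i] - cs[b.j]), abs=1e-9
        )
    # the closest inter-methyl H–H contact shrinks on eclipsing
    h1, h2 = (2, 3, 4), (5, 6, 7)
    def min_hh(c):
        return min(np.linalg.norm(c[i] - c[j]) for i in h1 for j in h2)
    assert min_hh(ce) < min_hh(cs) - 0.1


def test_ring_bond_is_not_rotatable(benzene):
    with pytest.raises(NonRotatableError):
        rotate_torsion(benzene, (5, 0, 1, 2), 30.0)


# ------------------------------------------------- energies

def test_vdw_minimum_at_combined_radius():
    x, d = get_element("H").uff_params
    system, cs = _point_charge_system(["H", "H"], [[0, 0, 0], [x, 0, 0]], [0, 0])
    e, comps = conformer_energy(system, cs)
    assert comps["E_vdw"] == pytest.approx(-d, abs=1e-12)
    assert comps["E_coul"] == 0.0


def test_single_atom_has_zero_energy():
    system, cs = _point_charge_system(["C"], [[0, 0, 0]], [0.5])
    e, comps = conformer_energy(system, cs)
    assert e == 0.0


def test_v2_term_cosine_closed_form():
    system = fx.ethane()
    perceive_covalent_bonds(system)
    t = _ethane_torsion(system)
    cs = ChargeSet("qeq", np.zeros(8), 0.0, 0.0)
    v2 = 3.0
    for phi, expected in ((0.0, 0.0), (90.0, v2), (180.0, 0.0)):
        conf = rotate_torsion(system, t, phi)
        _, comps = conformer_energy(conf, cs, [(t, v2)])
        assert comps["E_tors"] == pytest.approx(expected, abs=1e-9)


def test_components_sum_to_total():
    system = fx.biphenyl()
    perceive_covalent_bonds(system)
    cs = qeq_charges(system)
    rings = perceive_rings(system)
    br = find_bridge_bonds(system, rings)[0]
    oa = [n for n in system.neighbors(br.i) if n != br.j][0]
    ob = [n for n in system.neighbors(br.j) if n != br.i][0]
    t = (oa, br.i, br.j, ob)
    e, comps = conformer_energy(system, cs, [(t, 1.0)])
    assert e == pytest.approx(sum(comps.values()), abs=1e-10)


# ------------------------------------------------- scans

def _biphenyl_scan(step=90.0, twist=44.0):
    system = fx.biphenyl(twist=twist)
    perceive_covalent_bonds(system)
    rings = perceive_rings(system)
    br = find_bridge_bonds(system, rings)[0]
    oa = [n for n in system.neighbors(br.i) if n != br.j][0]
    ob = [n for n in system.neighbors(br.j) if n != br.i][0]
    t1 = (oa, br.i, br.j, ob)
    t2 = (ob, br.j, br.i, oa)
    cs = qeq_charges(system)
    return system, torsion_scan(system, t1, t2, cs, step=step, keep_frames=True)


def test_planar_biphenyl_energy_diverges():
    """The ortho-H overlap makes the coplanar conformations far higher in
    energy than the twisted ones."""
    _, surf = _biphenyl_scan(step=90.0)
    planar = surf.energies[0, 0]
    twisted = surf.energies[0, 1]  # φ₂ = 90°
    assert planar > twisted + 20.0


def test_scan_is_periodic_and_order_independent():
    system, surf = _biphenyl_scan(step=90.0)
    # φ and φ+360 give identical geometry: energy at column 0 equals the
    # energy recomputed after adding a full turn
    from molperceive.grids import rotate_torsion as rot

    assert np.allclose(surf.energies[:, 0], surf.energies[0, 0], atol=1e-8)


def test_scan_preserves_rigid_side_distances():
    system, surf = _biphenyl_scan(step=120.0)
    ring_a = list(range(11))  # ring A carbons + their hydrogens
    base = system.coords()
    d_ref = np.linalg.norm(base[ring_a][:, None] - base[ring_a][None, :], axis=-1)
    for frame in surf.frames:
        d = np.linalg.norm(frame[ring_a][:, None] - frame[ring_a][None, :], axis=-1)
        assert np.abs(d - d_ref).max() < 1e-9


def test_clash_points_get_sentinel():
    """Conformations whose closest non-bonded contact falls below the clash
    distance are flagged and pinned to the sentinel energy instead of being
    evaluated (here the planar biphenyl ortho-H contact, ~1.78 Å, with the
    clash distance raised above it)."""
    from molperceive.config import PerceptionConfig

    system = fx.biphenyl(twist=44.0)
    perceive_covalent_bonds(system)
    br = find_bridge_bonds(system, perceive_rings(system))[0]
    oa = [n for n in system.neighbors(br.i) if n != br.j][0]
    ob = [n for n in system.neighbors(br.j) if n != br.i][0]
    cs = ChargeSet("qeq", np.zeros(system.n_atoms), 0.0, 0.0)
    cfg = PerceptionConfig(clash_dist=1.9)
    surf = torsion_scan(system, (oa, br.i, br.j, ob), (ob, br.j, br.i, oa),
                        cs, step=90.0, config=cfg, keep_frames=False)
    assert surf.clash.any() and not surf.clash.all()
    assert np.all(surf.energies[surf.clash] == cfg.clash_energy)
    assert np.all(np.abs(surf.energies[~surf.clash]) < 1e4)


def test_step_must_divide_360():
    system = fx.ethane()
    perceive_covalent_bonds(system)
    cs = ChargeSet("qeq", np.zeros(8), 0.0, 0.0)
    with pytest.raises(ValueError, match="divide"):
        torsion_scan(system, (2, 0, 1, 5), (5, 1, 0, 2), cs, step=70.0)
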