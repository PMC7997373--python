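import itertools
import math

import numpy as np
import pytest

from molperceive import fixtures as fx
from molperceive.bond_perception import (
    angular_strength,
    calibrate_sigma,
    equilibrium_length,
    perceive_covalent_bonds,
    perceive_hydrogen_bonds,
    prune_excess_bonds,
    radial_strength,
)
from molperceive.chem_data import get_element
from molperceive.config import PerceptionConfig
from molperceive.core import Bond, MolecularSystem


# ------------------------------------------------- equilibrium length

def test_equilibrium_length_homonuclear_is_radii_sum():
    r_h = get_element("H").r_cov
    assert equilibrium_length("H", "H") == pytest.approx(2 * r_h)


def test_equilibrium_length_ch_hand_arithmetic():
    r = get_element("C").r_cov + get_element("H").r_cov
    dchi = abs(get_element("C").chi - get_element("H").chi)
    assert equilibrium_length("C", "H", c_en=0.09) == pytest.approx(r - 0.09 * dchi)
    assert equilibrium_length("C", "H") == equilibrium_length("H", "C")


def test_equilibrium_length_polar_pair_is_shortened():
    assert equilibrium_length("K", "O") < get_element("K").r_cov + get_element("O").r_cov


# ------------------------------------------------- strength profile

def test_radial_strength_plateau_and_calibration():
    sigma = calibrate_sigma(0.4, 0.4)
    assert radial_strength(1.0, 1.0, sigma) == 1.0
    assert radial_strength(0.5, 1.0, sigma) == 1.0
    assert radial_strength(1.4, 1.0, sigma) == pytest.approx(0.4, abs=1e-12)
    assert radial_strength(1.0 + 10 * sigma, 1.0, sigma) < 1e-10


def test_radial_strength_is_c1_at_the_plateau_edge():
    """Value and first derivative are continuous at r = r_e."""
    sigma = calibrate_sigma(0.4, 0.4)
    h = 1e-7
    left = (radial_strength(1.0, 1.0, sigma) - radial_strength(1.0 - h, 1.0, sigma)) / h
    right = (radial_strength(1.0 + h, 1.0, sigma) - radial_strength(1.0, 1.0, sigma)) / h
    assert abs(left) < 1e-6 and abs(right) < 1e-6
    assert radial_strength(1.0 - h, 1.0, sigma) == pytest.approx(
        radial_strength(1.0 + h, 1.0, sigma), abs=1e-9
    )


def test_radial_strength_strictly_decreasing_past_re():
    sigma = calibrate_sigma(0.4, 0.4)
    rs = radial_strength(np.linspace(1.0, 3.0, 50), 1.0, sigma)
    assert np.all(np.diff(rs) < 0)


def test_calibrate_sigma_properties():
    assert calibrate_sigma(0.4, math.exp(-0.5)) == pytest.approx(0.4, abs=1e-12)
    assert calibrate_sigma(0.4, 0.6) > calibrate_sigma(0.4, 0.4)  # monotone
    for bad in (0.0, 1.0, 1.5, -0.1):
        with pytest.raises(ValueError):
            calibrate_sigma(0.4, bad)


# ------------------------------------------------- covalent perception

def test_water_has_exactly_two_oh_bonds(water):
    bonds = water.bonds("covalent")
    assert len(bonds) == 2
    assert {frozenset(b.pair) for b in bonds} == {frozenset((0, 1)), frozenset((0, 2))}


def test_subthreshold_distance_is_skipped_as_clash():
    system = MolecularSystem.from_symbols_coords(["C", "C"], [[0, 0, 0], [0.3, 0, 0]])
    perceive_covalent_bonds(system)
    assert len(system.bonds()) == 0


def test_benzene_bond_count(benzene):
    assert len(benzene.bonds("covalent")) == 12


def test_stored_strengths_respect_bounds(benzene, water, methane):
    cfg = PerceptionConfig()
    for system in (benzene, water, methane):
        for b in system.bonds("covalent"):
            assert cfg.strength_threshold < b.strength <= 1.0


def test_permutation_invariance(rng):
    """Shuffling atom order never changes the perceived bond set."""
    base = fx.celecoxib()
    perceive_covalent_bonds(base)
    ref = {
        frozenset((base.atoms[b.i].serial, base.atoms[b.j].serial))
        for b in base.bonds("covalent")
    }
    perm = rng.permutation(base.n_atoms)
    atoms = [base.atoms[p] for p in perm]
    shuffled = MolecularSystem(atoms)
    perceive_covalent_bonds(shuffled)
    got = {
        frozenset((shuffled.atoms[b.i].serial, shuffled.atoms[b.j].serial))
        for b in shuffled.bonds("covalent")
    }
    assert got == ref


def test_neighbor_search_matches_all_pairs_reference(rng):
    """The KD-tree candidate search finds exactly the bonds of a brute-force
    O(n²) scan on random packings."""
    from molperceive.bond_perception import _candidate_pairs

    cfg = PerceptionConfig()
    sigma = calibrate_sigma(cfg.tolerance, cfg.strength_threshold)

    def accepted(pairs, symbols, coords):
        out = set()
        for i, j in pairs:
            d = float(np.linalg.norm(coords[i] - coords[j]))
            if d <= cfg.min_dist:
                continue
            r_e = equilibrium_length(symbols[i], symbols[j], cfg.c_en)
            if d <= r_e + cfg.tolerance and radial_strength(d, r_e, sigma) > cfg.strength_threshold:
                out.add((i, j))
        return out

    for _ in range(5):
        n = int(rng.integers(10, 50))
        symbols = list(rng.choice(["C", "N", "O", "H"], size=n))
        coords = rng.uniform(0, 8, size=(n, 3))
        brute = accepted(itertools.combinations(range(n), 2), symbols, coords)
        max_r = max(get_element(s).r_cov for s in set(symbols))
        tree = accepted(_candidate_pairs(coords, 2 * max_r + cfg.tolerance),
                        symbols, coords)
        assert tree == brute


def test_tolerance_monotonicity(methane):
    """Raising the tolerance never removes a perceived bond."""
    loose = PerceptionConfig(tolerance=0.6)
    base_pairs = {b.pair for b in methane.bonds("covalent")}
    system = fx.methane()
    perceive_covalent_bonds(system, loose)
    assert base_pairs <= {b.pair for b in system.bonds("covalent")}


# ------------------------------------------------- pruning

def test_prune_keeps_strongest_bond_on_hydrogen():
    system = MolecularSystem.from_symbols_coords(
        ["H", "O", "O"], [[0, 0, 0], [0.9, 0, 0], [-1.05, 0, 0]]
    )
    perceive_covalent_bonds(system)
    bonds = system.bonds("covalent")
    assert len(bonds) == 1
    assert bonds[0].pair == (0, 1)  # the shorter, stronger O–H wins


def test_prune_is_identity_within_valence(water):
    before = {b.pair for b in water.bonds("covalent")}
    prune_excess_bonds(water)
    assert {b.pair for b in water.bonds("covalent")} == before


def test_potassium_coordination_reduced_to_alkali_limit():
    """K⁺ octahedrally caged by six O at an ionic distance keeps only its
    single strongest contact (alkali max coordination 1)."""
    coords = [[0.0, 0.0, 0.0]]
    symbols = ["K"]
    d = 2.7
    for axis in range(3):
        for sign in (1, -1):
            p = [0.0, 0.0, 0.0]
            p[axis] = sign * d
            coords.append(p)
            symbols.append("O")
    # make one oxygen slightly closer so the survivor is well-defined
    coords[1][0] = 2.65
    system = MolecularSystem.from_symbols_coords(symbols, coords)
    perceive_covalent_bonds(system)
    k_bonds = [b for b in system.bonds("covalent") if 0 in b.pair]
    assert len(k_bonds) == 1
    assert k_bonds[0].pair == (0, 1)


# ------------------------------------------------- hydrogen bonds

def test_water_dimer_single_linear_hbond():
    system = fx.water_dimer(r_oo=2.9)
    perceive_covalent_bonds(system)
    perceive_hydrogen_bonds(system)
    hb = system.bonds("hydrogen")
    assert len(hb) == 1
    # O···O at exactly r_e and θ = 180° → radial 1 × angular 1
    assert hb[0].strength == pytest.approx(1.0, abs=1e-9)
    # the hydrogen-bonded pair is donor H (index 1) and acceptor O (index 3)
    assert hb[0].pair == (1, 3)


def test_ch_groups_are_not_donors():
    methane = fx.methane()
    water = fx.water(origin=(3.0, 0.0, 0.0))
    system = MolecularSystem.from_symbols_coords(
        methane.symbols() + water.symbols(),
        np.vstack([methane.coords(), water.coords()]),
    )
    perceive_covalent_bonds(system)
    perceive_hydrogen_bonds(system)
    donors = {b.pair for b in system.bonds("hydrogen")}
    # any perceived hydrogen bond must involve water's own H, never methane C–H
    assert all(i not in range(1, 5) for pair in donors for i in pair)


def test_bent_geometry_suppressed_by_angular_term():
    # donor O–H along +x, acceptor placed so θ(D–H–A) ≈ 90°
    system = MolecularSystem.from_symbols_coords(
        ["O", "H", "O", "H", "H"],
        [[0, 0, 0], [0.96, 0, 0], [0.96, 2.9, 0], [1.6, 3.6, 0], [0.2, 3.6, 0]],
    )
    perceive_covalent_bonds(system)
    perceive_hydrogen_bonds(system)
    assert len(system.bonds("hydrogen")) == 0


def test_hbonds_do_not_touch_covalent_topology():
    system = fx.water_dimer()
    perceive_covalent_bonds(system)
    before = {b.pair for b in system.bonds("covalent")}
    perceive_hydrogen_bonds(system)
    assert {b.pair for b in system.bonds("covalent")} == before


def test_angular_strength_calibration():
    sigma_t = 60.0 / math.sqrt(-2.0 * math.log(0.4))
    assert angular_strength(180.0, 180.0, sigma_t) == 1.0
    assert angular_strength(120.0, 180.0, sigma_t) == pytest.approx(0.4, abs=1e-12)
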