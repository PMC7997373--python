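"""Continuous covalent and hydrogen bond perception.

A candidate bond gets a strength in (0, 1] from a plateau-Gaussian radial
profile: 1 up to the equilibrium length r_e, then a Gaussian decay with a
width calibrated so that the strength equals the acceptance threshold
exactly at r_e + tolerance.  The profile is continuous with a continuous
first derivative at r_e (both sides have zero slope there).

r_e is the Schomaker–Stevenson electronegativity-corrected radii sum

    r_e(a, b) = R_cov(a) + R_cov(b) − c_en · |χ_a − χ_b|

which shortens the reference length for polar pairs and is what keeps
ionic contacts (e.g. K⁺···O) from being over-bonded.  Pairs whose strength
exceeds the threshold become covalent bonds; atoms left with more bonds
than their allowed coordination lose their weakest bonds.

Hydrogen bonds reuse the same radial profile on the donor–acceptor
heavy-atom distance, multiplied by an angular plateau-Gaussian in the
donor–H–acceptor angle centred at 180°.  N and O act as both donors and
acceptors.
"""

from __future__ import annotations

import logging
import math

import numpy as np
from scipy.spatial import cKDTree

from .config import PerceptionConfig
from .core import Bond, MolecularSystem

__all__ = [
    "equilibrium_length",
    "radial_strength",
    "angular_strength",
    "calibrate_sigma",
    "perceive_covalent_bonds",
    "prune_excess_bonds",
    "perceive_hydrogen_bonds",
    "perceive",
]

log = logging.getLogger(__name__)

_HBOND_ELEMENTS = {"N", "O"}


def equilibrium_length(a: str, b: str, c_en: float = 0.09, table=None) -> float:
    """Electronegativity-corrected equilibrium single-bond length (Å).

    Floored at 0.4·(radii sum) so pathological electronegativity tables
    cannot produce nonphysical lengths; unreachable for real element pairs.
    """
    if table is None:
        from .chem_data import default_table

        table = default_table()
    ra, rb = table.get(a).r_cov, table.get(b).r_cov
    raw = ra + rb - c_en * table.chi_difference(a, b)
    return max(raw, 0.4 * (ra + rb))


def calibrate_sigma(tolerance: float, threshold: float) -> float:
    """Width making the Gaussian tail pass through (r_e + tolerance, threshold)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    if tolerance <= 0:
        raise ValueError(f"tolerance must be positive, got {tolerance}")
    return tolerance / math.sqrt(-2.0 * math.log(threshold))


def radial_strength(r, r_e: float, sigma_r: float):
    """Plateau-Gaussian radial score: 1 on [0, r_e], Gaussian decay beyond."""
    r = np.asarray(r, dtype=float)
    excess = np.maximum(r - r_e, 0.0)
    out = np.exp(-(excess**2) / (2.0 * sigma_r**2))
    return float(out) if out.ndim == 0 else out


def angular_strength(theta, theta_e: float, sigma_theta: float):
    """Angular score with the same plateau-Gaussian form, in degrees."""
    theta = np.asarray(theta, dtype=float)
    dev = np.maximum(np.abs(theta_e - theta), 0.0)
    out = np.exp(-(dev**2) / (2.0 * sigma_theta**2))
    return float(out) if out.ndim == 0 else out


def _candidate_pairs(coords: np.ndarray, cutoff: float):
    """All index pairs closer than ``cutoff``, via a KD-tree."""
    tree = cKDTree(coords)
    return sorted(tuple(sorted(p)) for p in tree.query_pairs(cutoff))


def perceive_covalent_bonds(
    system: MolecularSystem, config: PerceptionConfig | None = None
) -> MolecularSystem:
    """Assign covalent bonds by continuous strength, then prune to valence.

    Mutates and returns ``system``.  Deterministic and independent of atom
    ordering (pairs are evaluated symmetrically; pruning has total
    tie-breaking).
    """
    cfg = config or PerceptionConfig()
    table = system.table
    sigma = calibrate_sigma(cfg.tolerance, cfg.strength_threshold)
    coords = system.coords()
    symbols = system.symbols()

    max_r_cov = max(table.get(s).r_cov for s in set(symbols))
    cutoff = 2.0 * max_r_cov + cfg.tolerance  # any candidate r_e + tol fits

    system.clear_bonds("covalent")
    for i, j in _candidate_pairs(coords, cutoff):
        d = float(np.linalg.norm(coords[i] - coords[j]))
        if d <= cfg.min_dist:
            log.warning(
                "suspected clash: atoms %d-%d at %.3f Å (< %.2f Å), skipped",
                system.atoms[i].serial, system.atoms[j].serial, d, cfg.min_dist,
            )
            continue
        r_e = equilibrium_length(symbols[i], symbols[j], cfg.c_en, table)
        if d > r_e + cfg.tolerance:
            continue
        s = radial_strength(d, r_e, sigma)
        if s > cfg.strength_threshold:
            system.add_bond(
                Bond(i, j, kind="covalent", strength=s, length=d, r_e=r_e)
            )
    return prune_excess_bonds(system)


def prune_excess_bonds(system: MolecularSystem) -> MolecularSystem:
    """Drop the weakest bonds of any over-coordinated atom.

    Ties broken by longer bond first, then by smaller index pair, so the
    result does not depend on insertion order.
    """
    table = system.table
    while True:
        worst = None
        for idx in range(system.n_atoms):
            limit = table.get(system.atoms[idx].symbol).max_coordination
            neigh = system.neighbors(idx, "covalent")
            if len(neigh) <= limit:
                continue
            incident = [system.get_bond(idx, j) for j in neigh]
            # weakest first; among equals the longer, then lower index pair
            cand = min(incident, key=lambda b: (b.strength, -b.length, b.pair))
            if worst is None or (cand.strength, -cand.length, cand.pair) < (
                worst.strength, -worst.length, worst.pair
            ):
                worst = cand
        if worst is None:
            return system
        system.remove_bond(*worst.pair)


def _hbond_r_e(cfg: PerceptionConfig, donor_sym: str, acceptor_sym: str) -> float:
    pair = frozenset((donor_sym, acceptor_sym))
    if pair == frozenset(("O",)):
        return cfg.hbond_r_e_oo
    if pair == frozenset(("N",)):
        return cfg.hbond_r_e_nn
    return cfg.hbond_r_e_on


def perceive_hydrogen_bonds(
    system: MolecularSystem, config: PerceptionConfig | None = None
) -> MolecularSystem:
    """Add hydrogen bonds (H···acceptor pairs) to a covalently-bonded system.

    Strength = radial(donor–acceptor distance) × angular(donor–H–acceptor
    angle).  Never alters covalent topology.
    """
    cfg = config or PerceptionConfig()
    coords = system.coords()
    symbols = system.symbols()
    sigma_r = calibrate_sigma(cfg.tolerance, cfg.hbond_threshold)
    sigma_t = cfg.hbond_theta_tol / math.sqrt(-2.0 * math.log(cfg.hbond_threshold))

    system.clear_bonds("hydrogen")
    donors = []  # (donor index, hydrogen index)
    for h in range(system.n_atoms):
        if symbols[h] != "H":
            continue
        for d in system.neighbors(h, "covalent"):
            if symbols[d] in _HBOND_ELEMENTS:
                donors.append((d, h))

    for d, h in donors:
        h_neighbors = set(system.neighbors(h, "covalent"))
        for a in range(system.n_atoms):
            if a == d or a == h or symbols[a] not in _HBOND_ELEMENTS:
                continue
            if a in h_neighbors:
                continue
            r_da = float(np.linalg.norm(coords[d] - coords[a]))
            r_e = _hbond_r_e(cfg, symbols[d], symbols[a])
            radial = radial_strength(r_da, r_e, sigma_r)
            if radial <= cfg.hbond_threshold:
                continue
            v1 = coords[d] - coords[h]
            v2 = coords[a] - coords[h]
            cos_t = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
            theta = math.degrees(math.acos(max(-1.0, min(1.0, cos_t))))
            s = radial * angular_strength(theta, cfg.hbond_theta_e, sigma_t)
            if s > cfg.hbond_threshold:
                system.add_bond(
                    Bond(h, a, kind="hydrogen", strength=float(s),
                         length=system.distance(h, a), r_e=r_e)
                )
    return system


def perceive(system: MolecularSystem, config: PerceptionConfig | None = None,
             hbonds: bool = False) -> MolecularSystem:
    """Covalent (and optionally hydrogen) bond perception in one call."""
    perceive_covalent_bonds(system, config)
    if hbonds:
        perceive_hydrogen_bonds(system, config)
    return system
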