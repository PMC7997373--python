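"""Biaryl bridges: find them, cut capped local-geometry fragments, and
attach a 2-fold torsional parameter per bridge.

A bridge bond joins an atom of one planar ring to an atom of a different
planar ring while not itself being an edge of any ring — the latter clause
is what keeps fused systems (naphthalene) bridge-free while biphenyl-like
axes are reported.  Fragments keep every atom within a graph-distance
radius of either bridge atom; each severed bond is healed with a hydrogen
cap placed along the original bond direction at the sum of the two covalent
radii.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping

import networkx as nx
import numpy as np

from .config import PerceptionConfig
from .core import Atom, Bond, MolecularSystem
from .ring_perception import Ring

__all__ = ["BridgeBond", "Fragment", "find_bridge_bonds", "cut_fragment",
           "v2_parameter", "TableV2Provider", "LinearV2Provider"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BridgeBond:
    i: int
    j: int
    ring_i: Ring
    ring_j: Ring
    serials: tuple[int, int]


@dataclass
class Fragment:
    system: MolecularSystem
    origin_map: dict[int, int]  # fragment atom index -> parent atom index
    bridge: BridgeBond  # in fragment numbering


def find_bridge_bonds(system: MolecularSystem, rings: list[Ring]) -> list[BridgeBond]:
    """Non-ring covalent bonds joining two distinct planar rings."""
    ring_edges: set[tuple[int, int]] = set()
    for ring in rings:
        ring_edges |= ring.edge_set
    planar = [r for r in rings if r.planar]
    skipped_nonplanar = 0

    found: dict[tuple[int, int], BridgeBond] = {}
    for a in range(len(rings)):
        for b in range(a + 1, len(rings)):
            r1, r2 = rings[a], rings[b]
            for i in r1.atoms:
                for j in r2.atoms:
                    bond = system.get_bond(i, j)
                    if bond is None or bond.kind != "covalent":
                        continue
                    pair = bond.pair
                    if pair in ring_edges or pair in found:
                        continue
                    if not (r1.planar and r2.planar):
                        skipped_nonplanar += 1
                        continue
                    found[pair] = BridgeBond(
                        i=pair[0], j=pair[1],
                        ring_i=r1 if pair[0] in r1.atoms else r2,
                        ring_j=r2 if pair[1] in r2.atoms else r1,
                        serials=(system.atoms[pair[0]].serial,
                                 system.atoms[pair[1]].serial),
                    )
    if skipped_nonplanar:
        log.info("skipped %d inter-ring bond(s) involving non-planar rings",
                 skipped_nonplanar)
    return [found[k] for k in sorted(found)]


def cut_fragment(system: MolecularSystem, bridge: BridgeBond, depth: int = 4,
                 config: PerceptionConfig | None = None) -> Fragment:
    """Cut the molecule around a bridge bond at a graph-distance radius.

    Atoms within ``depth`` bonds of either bridge atom are kept (set
    union when the two spheres overlap); every kept↔removed bond becomes a
    hydrogen cap on the original bond vector at r_cov(kept) + r_cov(H).
    """
    if depth < 1:
        raise ValueError(f"cut depth must be >= 1, got {depth}")
    g = system.covalent_graph()
    keep: set[int] = set()
    for root in (bridge.i, bridge.j):
        dist = nx.single_source_shortest_path_length(g, root, cutoff=depth)
        keep |= set(dist)
    keep_sorted = sorted(keep)
    new_index = {old: new for new, old in enumerate(keep_sorted)}
    table = system.table
    coords = system.coords()
    r_h = table.get("H").r_cov

    atoms: list[Atom] = []
    origin_map: dict[int, int] = {}
    for new, old in enumerate(keep_sorted):
        a = system.atoms[old]
        atoms.append(Atom(serial=new + 1, symbol=a.symbol, xyz=a.xyz))
        origin_map[new] = old

    frag_bonds: list[Bond] = []
    caps: list[tuple[int, int]] = []  # (kept old index, removed old index)
    for bond in system.bonds("covalent"):
        in_i, in_j = bond.i in keep, bond.j in keep
        if in_i and in_j:
            frag_bonds.append(
                Bond(new_index[bond.i], new_index[bond.j], kind="covalent",
                     strength=bond.strength, length=bond.length,
                     r_e=bond.r_e, order=bond.order)
            )
        elif in_i or in_j:
            kept, removed = (bond.i, bond.j) if in_i else (bond.j, bond.i)
            caps.append((kept, removed))

    for kept, removed in sorted(caps):
        direction = coords[removed] - coords[kept]
        direction = direction / np.linalg.norm(direction)
        cap_len = table.get(system.atoms[kept].symbol).r_cov + r_h
        pos = coords[kept] + cap_len * direction
        cap_new = len(atoms)
        atoms.append(Atom(serial=cap_new + 1, symbol="H",
                          xyz=(float(pos[0]), float(pos[1]), float(pos[2]))))
        origin_map[cap_new] = removed  # caps map to the atom they replaced
        frag_bonds.append(
            Bond(new_index[kept], cap_new, kind="covalent",
                 strength=1.0, length=cap_len, r_e=cap_len, order=1.0)
        )

    frag = MolecularSystem(atoms, provenance=f"fragment:{system.provenance}",
                           table=table)
    for b in frag_bonds:
        frag.add_bond(b)
    frag_bridge = BridgeBond(
        i=new_index[bridge.i], j=new_index[bridge.j],
        ring_i=bridge.ring_i, ring_j=bridge.ring_j,
        serials=(new_index[bridge.i] + 1, new_index[bridge.j] + 1),
    )
    return Fragment(system=frag, origin_map=origin_map, bridge=frag_bridge)


# ---------------------------------------------------------------------------
# V2 torsional parameter providers

class TableV2Provider:
    """Looks bridges up by their source serial pair; optional default."""

    def __init__(self, table: Mapping[tuple[int, int], float],
                 default: float | None = None):
        self.table = {tuple(sorted(k)): v for k, v in table.items()}
        self.default = default
        self.calibrated = True

    def __call__(self, system: MolecularSystem, bridge: BridgeBond) -> float:
        key = tuple(sorted(bridge.serials))
        if key in self.table:
            return self.table[key]
        if self.default is not None:
            return self.default
        raise KeyError(f"no V2 parameter for bridge with serials {key}")


class LinearV2Provider:
    """Uncalibrated built-in default: V2 = α·|Δχ(bridge atoms)| + β.

    Stands in for an external electronegativity→V2 regression; outputs are
    labelled uncalibrated until real coefficients are supplied.
    """

    calibrated = False

    def __init__(self, alpha: float = 1.0, beta: float = 0.0):
        self.alpha = alpha
        self.beta = beta

    def __call__(self, system: MolecularSystem, bridge: BridgeBond) -> float:
        dchi = system.table.chi_difference(
            system.atoms[bridge.i].symbol, system.atoms[bridge.j].symbol
        )
        return self.alpha * dchi + self.beta


def v2_parameter(system: MolecularSystem, bridge: BridgeBond,
                 provider: Callable | None = None,
                 config: PerceptionConfig | None = None) -> tuple[float, bool]:
    """2-fold torsion coefficient (kcal/mol) for a bridge.

    Returns (value, calibrated).  With no provider, the built-in linear
    Δχ map is used and flagged uncalibrated.
    """
    cfg = config or PerceptionConfig()
    if provider is None:
        provider = LinearV2Provider(cfg.v2_alpha, cfg.v2_beta)
    value = float(provider(system, bridge))
    calibrated = bool(getattr(provider, "calibrated", False))
    if not calibrated:
        log.warning("V2 for bridge %s is uncalibrated (built-in linear map)",
                    bridge.serials)
    return value, calibrated
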