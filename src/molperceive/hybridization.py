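"""Hybridization assignment from bond angles, rings, and bond lengths.

Precedence: planar-ring membership forces sp2; atoms with two or more
bonds use a mean-bond-angle heuristic (≥155° sp, ≥115° sp2, else sp3, the
cutoffs sitting midway between ideal 180/120/109.5° geometries); terminal
atoms are `unknown` except O, N, and C, whose single bond length is tested
against Pyykkö double/triple radii sums; configured transition elements
get the sentinel label `metal`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import PerceptionConfig
from .core import MolecularSystem
from .ring_perception import Ring

__all__ = ["atom_angle_stats", "assign_hybridization", "AngleStats"]


@dataclass(frozen=True)
class AngleStats:
    min_angle: float
    max_angle: float
    mean_angle: float
    n_bonds: int


def atom_angle_stats(system: MolecularSystem, atom_index: int) -> AngleStats:
    """Min/max/mean bond angle (degrees) over all neighbour pairs at an atom."""
    neigh = system.neighbors(atom_index, "covalent")
    if len(neigh) < 2:
        return AngleStats(float("nan"), float("nan"), float("nan"), len(neigh))
    coords = system.coords()
    center = coords[atom_index]
    angles = []
    for a in range(len(neigh)):
        for b in range(a + 1, len(neigh)):
            v1 = coords[neigh[a]] - center
            v2 = coords[neigh[b]] - center
            cos_t = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
            angles.append(math.degrees(math.acos(max(-1.0, min(1.0, cos_t)))))
    return AngleStats(min(angles), max(angles), float(np.mean(angles)), len(neigh))


def _terminal_label(system: MolecularSystem, i: int, neighbor: int,
                    cfg: PerceptionConfig) -> str:
    """Bond-length test for terminal O/N/C against multiple-bond radii sums."""
    sym = system.atoms[i].symbol
    if sym not in ("O", "N", "C"):
        return "unknown"
    table = system.table
    rec_i = table.get(sym)
    rec_j = table.get(system.atoms[neighbor].symbol)
    d = system.distance(i, neighbor)

    def radii_sum(attr: str) -> float | None:
        ri = getattr(rec_i, attr)
        rj = getattr(rec_j, attr)
        if ri is None or rj is None:
            return None
        return ri + rj

    if sym in ("N", "C"):
        triple = radii_sum("r_pyykko_t")
        if triple is not None and d <= triple + cfg.terminal_slack:
            return "sp"
    double = radii_sum("r_pyykko_d")
    if double is not None and d <= double + cfg.terminal_slack:
        return "sp2"
    return "sp3"


def assign_hybridization(system: MolecularSystem, rings: list[Ring],
                         config: PerceptionConfig | None = None) -> list[str]:
    """Label every atom sp/sp2/sp3/unknown/metal; stores on the system too."""
    cfg = config or PerceptionConfig()
    planar_members: set[int] = set()
    for ring in rings:
        if ring.planar:
            planar_members.update(ring.atoms)

    labels: list[str] = []
    for i, atom in enumerate(system.atoms):
        if atom.symbol in cfg.metals:
            labels.append("metal")
            continue
        if i in planar_members:
            labels.append("sp2")
            continue
        neigh = system.neighbors(i, "covalent")
        if len(neigh) >= 2:
            stats = atom_angle_stats(system, i)
            if stats.mean_angle >= cfg.sp_cutoff:
                labels.append("sp")
            elif stats.mean_angle >= cfg.sp2_cutoff:
                labels.append("sp2")
            else:
                labels.append("sp3")
        elif len(neigh) == 1:
            labels.append(_terminal_label(system, i, neigh[0], cfg))
        else:
            labels.append("unknown")  # isolated atom (ion, monoatomic)
    system.hybridization = labels
    return labels
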