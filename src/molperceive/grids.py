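"""Electrostatic-potential voxel grids and rigid two-torsion energy scans.

The scan energy model is deliberately minimal — the non-bonded part of a
force field plus the bridge torsion term:

    E = Σ D_ij[(x_ij/r)¹² − 2(x_ij/r)⁶]  (UFF 12-6, geometric combination)
      + k Σ q_i q_j / r                  (Coulomb, kcal/mol with k = 332.06)
      + Σ V2/2 · (1 − cos 2φ)            (2-fold torsion, barrier at 90°)

1-2 and 1-3 pairs are excluded; 1-4 pairs enter unscaled (the UFF
convention).  Rotations are rigid: removing the central bond bipartitions
the covalent graph and the side holding the fourth torsion atom turns about
the bond axis, so all intra-side internal coordinates are preserved
exactly.  Every grid point of a scan rotates from the same reference
conformation, making the surface independent of evaluation order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .chem_data import ParameterizationError
from .charges import ChargeSet
from .config import PerceptionConfig
from .core import MolecularSystem
from .ring_perception import dihedral_angle

__all__ = ["VoxelGrid", "TorsionSurface", "esp_grid", "rotate_torsion",
           "conformer_energy", "torsion_scan", "NonRotatableError"]

log = logging.getLogger(__name__)

COULOMB_KCAL = 332.0637  # e²/(4πε₀) in kcal·Å/(mol·e²)
HARTREE_BOHR = 0.52917721067  # Å per Bohr (for the hartree_e unit system)


class NonRotatableError(ValueError):
    """The central bond of a torsion lies in a ring; rotation is undefined."""


@dataclass
class VoxelGrid:
    origin: tuple[float, float, float]  # Å
    axes: tuple  # three orthogonal step vectors, Å
    counts: tuple[int, int, int]
    values: np.ndarray  # shape == counts

    def points(self) -> np.ndarray:
        """Cartesian centres of all voxels, shape (nx, ny, nz, 3)."""
        o = np.asarray(self.origin, dtype=float)
        ax = np.asarray(self.axes, dtype=float)
        nx_, ny_, nz_ = self.counts
        ii, jj, kk = np.meshgrid(
            np.arange(nx_), np.arange(ny_), np.arange(nz_), indexing="ij"
        )
        return (o + ii[..., None] * ax[0] + jj[..., None] * ax[1]
                + kk[..., None] * ax[2])


@dataclass
class TorsionSurface:
    phi1_grid: np.ndarray  # degrees
    phi2_grid: np.ndarray
    energies: np.ndarray  # kcal/mol, shape (len(phi1), len(phi2))
    components: dict[str, np.ndarray]  # E_vdw, E_coul, E_tors
    clash: np.ndarray  # boolean mask
    frames: list  # per-point coordinate arrays, row-major over (phi1, phi2)


def esp_grid(system: MolecularSystem, charges: ChargeSet,
             origin, extents, spacing: float,
             units: str = "e_per_angstrom") -> VoxelGrid:
    """Coulomb potential V(p) = k Σ qᵢ/|p − rᵢ| on a regular grid.

    ``extents`` are the box edge lengths (Å) along x, y, z.  Units:
    ``e_per_angstrom`` (k = 1, e/Å) or ``hartree_e`` (atomic units).
    Voxels closer than 1e-6 Å to an atom are evaluated at that floor.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    extents = np.asarray(extents, dtype=float)
    if np.any(extents <= 0):
        raise ValueError("empty bounding box")
    counts = tuple(int(math.floor(e / spacing)) + 1 for e in extents)
    axes = (np.array([spacing, 0.0, 0.0]), np.array([0.0, spacing, 0.0]),
            np.array([0.0, 0.0, spacing]))
    grid = VoxelGrid(tuple(float(v) for v in origin), axes, counts,
                     np.zeros(counts))
    pts = grid.points().reshape(-1, 3)
    coords = system.coords()
    q = np.asarray(charges.charges, dtype=float)
    d = np.linalg.norm(pts[:, None, :] - coords[None, :, :], axis=-1)
    n_floored = int(np.count_nonzero(d < 1e-6))
    if n_floored:
        log.warning("%d voxel-atom distances floored at 1e-6 Å", n_floored)
    d = np.maximum(d, 1e-6)
    if units == "e_per_angstrom":
        k = 1.0
    elif units == "hartree_e":
        k = HARTREE_BOHR  # q/r with r in Bohr == 0.529177·q/r[Å]
    else:
        raise ValueError(f"unknown unit system {units!r}")
    grid.values = (k * (d ** -1 @ q)).reshape(counts)
    return grid


def _split_sides(system: MolecularSystem, b: int, c: int) -> np.ndarray:
    """Mask of atoms on the c-side after removing bond b–c; errors if b–c
    lies on a cycle."""
    g = system.covalent_graph()
    if not g.has_edge(b, c):
        raise ValueError(f"atoms {b} and {c} are not bonded")
    g.remove_edge(b, c)
    if nx.has_path(g, b, c):
        raise NonRotatableError(
            f"bond {b}-{c} is part of a ring and cannot be rotated"
        )
    side = nx.node_connected_component(g, c)
    mask = np.zeros(system.n_atoms, dtype=bool)
    mask[list(side)] = True
    return mask


def rotate_torsion(system: MolecularSystem, torsion: tuple[int, int, int, int],
                   angle: float) -> MolecularSystem:
    """Set a dihedral to ``angle`` degrees by rigid rotation (returns a copy).

    The side of the graph containing the fourth atom rotates about the
    axis through the two central atoms; all internal coordinates within
    each side are untouched.
    """
    a, b, c, d = torsion
    mask = _split_sides(system, b, c)
    coords = system.coords()
    current = dihedral_angle(coords[a], coords[b], coords[c], coords[d])
    delta = math.radians(angle - current)

    axis = coords[c] - coords[b]
    axis = axis / np.linalg.norm(axis)
    # Rodrigues rotation about the b→c axis through point b
    k = axis
    rel = coords[mask] - coords[b]
    cos_t, sin_t = math.cos(delta), math.sin(delta)
    rot = (rel * cos_t + np.cross(k, rel) * sin_t
           + np.outer(rel @ k, k) * (1.0 - cos_t))
    out = system.copy()
    new_coords = coords.copy()
    new_coords[mask] = rot + coords[b]
    out.set_coords(new_coords)
    return out


def conformer_energy(system: MolecularSystem, charges: ChargeSet,
                     v2_terms: list[tuple[tuple[int, int, int, int], float]] = (),
                     config: PerceptionConfig | None = None):
    """Non-bonded + 2-fold torsion energy of one conformation (kcal/mol).

    Returns (E_total, components dict).  1-2/1-3 pairs are excluded from
    both the 12-6 and Coulomb sums.
    """
    cfg = config or PerceptionConfig()
    n = system.n_atoms
    coords = system.coords()
    q = np.asarray(charges.charges, dtype=float)

    x = np.empty(n)
    dwell = np.empty(n)
    for i, atom in enumerate(system.atoms):
        params = system.table.get(atom.symbol).uff_params
        if params is None:
            raise ParameterizationError(f"no UFF parameters for element {atom.symbol}")
        x[i], dwell[i] = params

    g = system.covalent_graph()
    excluded = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in g[i]:
            excluded[i, j] = True  # 1-2
            for k in g[j]:
                if k != i:
                    excluded[i, k] = True  # 1-3
    np.fill_diagonal(excluded, True)

    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    iu = np.triu_indices(n, 1)
    pair_ok = ~excluded[iu]
    r = d[iu][pair_ok]
    e_vdw = e_coul = 0.0
    if r.size:
        xi = np.sqrt(x[iu[0][pair_ok]] * x[iu[1][pair_ok]])
        di = np.sqrt(dwell[iu[0][pair_ok]] * dwell[iu[1][pair_ok]])
        frac6 = (xi / r) ** 6
        e_vdw = float(np.sum(di * (frac6**2 - 2.0 * frac6)))
        e_coul = float(COULOMB_KCAL * np.sum(
            q[iu[0][pair_ok]] * q[iu[1][pair_ok]] / r
        ))

    e_tors = 0.0
    for (a, b, c, dd), v2 in v2_terms:
        phi = math.radians(dihedral_angle(coords[a], coords[b], coords[c], coords[dd]))
        e_tors += 0.5 * v2 * (1.0 - math.cos(2.0 * phi))

    comps = {"E_vdw": e_vdw, "E_coul": e_coul, "E_tors": e_tors}
    return e_vdw + e_coul + e_tors, comps


def torsion_scan(system: MolecularSystem,
                 t1: tuple[int, int, int, int],
                 t2: tuple[int, int, int, int],
                 charges: ChargeSet,
                 v2_terms: list[tuple[tuple[int, int, int, int], float]] = (),
                 step: float | None = None,
                 config: PerceptionConfig | None = None,
                 keep_frames: bool = True) -> TorsionSurface:
    """Rigid 2-D PES over (φ₁, φ₂) ∈ [0°, 360°) at a uniform step.

    Each point rotates both torsions from the input conformation, then
    evaluates :func:`conformer_energy`.  Points with any non-bonded pair
    closer than the clash distance get the sentinel energy and a flag.
    """
    cfg = config or PerceptionConfig()
    step = step if step is not None else cfg.scan_step
    if step <= 0 or abs(360.0 / step - round(360.0 / step)) > 1e-9:
        raise ValueError(f"step must divide 360, got {step}")
    for t in (t1, t2):
        _split_sides(system, t[1], t[2])  # raises NonRotatableError early

    phis = np.arange(0.0, 360.0, step)
    npts = len(phis)
    energies = np.zeros((npts, npts))
    comps = {k: np.zeros((npts, npts)) for k in ("E_vdw", "E_coul", "E_tors")}
    clash = np.zeros((npts, npts), dtype=bool)
    frames = []

    g = system.covalent_graph()
    bonded = {tuple(sorted(e)) for e in g.edges}
    n = system.n_atoms

    for i1, p1 in enumerate(phis):
        sys1 = rotate_torsion(system, t1, float(p1))
        for i2, p2 in enumerate(phis):
            conf = rotate_torsion(sys1, t2, float(p2))
            coords = conf.coords()
            d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
            iu = np.triu_indices(n, 1)
            nonbonded = np.array(
                [tuple(p) not in bonded for p in zip(*iu)]
            )
            if np.any(d[iu][nonbonded] < cfg.clash_dist):
                clash[i1, i2] = True
                energies[i1, i2] = cfg.clash_energy
                log.info("clash at (%.0f°, %.0f°), sentinel energy applied", p1, p2)
            else:
                e, c = conformer_energy(conf, charges, v2_terms, cfg)
                energies[i1, i2] = e
                for k, v in c.items():
                    comps[k][i1, i2] = v
            if keep_frames:
                frames.append(coords)
    return TorsionSurface(phis, phis.copy(), energies, comps, clash, frames)
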