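"""Ring perception: block partitioning + Horton minimum cycle basis.

The covalent graph is first reduced to its cyclic blocks (biconnected
components that actually contain a cycle); Horton's algorithm then runs per
block, which keeps its unfavourable worst-case complexity confined to the
small cyclic cores of otherwise tree-like systems such as proteins.

Horton's candidate set is one cycle per (vertex v, edge (x, y)) built from
BFS shortest paths, SP(v, x) + (x, y) + SP(y, v); candidates are sorted by
length and greedily accepted while linearly independent over the GF(2) edge
space, which yields a cycle basis of minimum total weight.  All tie-breaks
(BFS parent choice, candidate ordering) are by lowest index, so the basis
is reproducible even though a minimum cycle basis is generally not unique.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .config import PerceptionConfig
from .core import MolecularSystem

__all__ = ["Block", "Ring", "find_blocks", "horton_mcb",
           "classify_ring_planarity", "perceive_rings", "dihedral_angle"]

log = logging.getLogger(__name__)


@dataclass
class Block:
    """A cyclic biconnected subgraph of the covalent graph."""

    atom_indices: frozenset[int]
    edges: frozenset[tuple[int, int]]

    @property
    def cyclomatic_number(self) -> int:
        return len(self.edges) - len(self.atom_indices) + 1


@dataclass
class Ring:
    """An elementary cycle: ordered atom indices, consecutive ones bonded."""

    atoms: tuple[int, ...]
    planar: bool = False
    mean_torsion: float = float("nan")

    @property
    def size(self) -> int:
        return len(self.atoms)

    @property
    def edge_set(self) -> frozenset[tuple[int, int]]:
        n = len(self.atoms)
        return frozenset(
            tuple(sorted((self.atoms[k], self.atoms[(k + 1) % n]))) for k in range(n)
        )


def find_blocks(system_or_graph) -> list[Block]:
    """Cyclic biconnected components of the covalent graph.

    Bridges and acyclic parts are excluded; blocks share at most cut
    vertices.  Returned sorted by smallest atom index for determinism.
    """
    if isinstance(system_or_graph, MolecularSystem):
        g = system_or_graph.covalent_graph()
    else:
        g = system_or_graph
    blocks = []
    for comp_edges in nx.biconnected_component_edges(g):
        edges = frozenset(tuple(sorted(e)) for e in comp_edges)
        verts = frozenset(v for e in edges for v in e)
        if len(edges) >= len(verts):  # cyclic iff |E| ≥ |V| when biconnected
            blocks.append(Block(atom_indices=verts, edges=edges))
    return sorted(blocks, key=lambda b: min(b.atom_indices))


def _bfs_tree(adj: dict[int, list[int]], root: int) -> dict[int, int | None]:
    """Deterministic BFS parents: neighbours visited in ascending order."""
    parent: dict[int, int | None] = {root: None}
    frontier = [root]
    while frontier:
        nxt = []
        for v in frontier:
            for w in adj[v]:
                if w not in parent:
                    parent[w] = v
                    nxt.append(w)
        frontier = nxt
    return parent


def _path_to_root(parent: dict[int, int | None], v: int) -> list[int]:
    path = [v]
    while parent[path[-1]] is not None:
        path.append(parent[path[-1]])
    return path


def horton_mcb(block: Block, max_ring_size: int | None = None) -> list[Ring]:
    """Minimum cycle basis of one block by Horton's algorithm.

    Returns exactly ``cyclomatic_number`` rings (fewer only if a size cap
    removed necessary candidates, which is logged).
    """
    verts = sorted(block.atom_indices)
    edges = sorted(block.edges)
    adj: dict[int, list[int]] = {v: [] for v in verts}
    for a, b in edges:
        adj[a].append(b)
        adj[b].append(a)
    for v in verts:
        adj[v].sort()
    edge_bit = {e: 1 << k for k, e in enumerate(edges)}
    target = block.cyclomatic_number

    # Candidate cycles: one per (vertex, edge) from shortest paths.
    seen: set[frozenset] = set()
    candidates: list[tuple[int, tuple[int, ...], int]] = []  # (len, atoms, bitset)
    trees = {v: _bfs_tree(adj, v) for v in verts}
    for v in verts:
        parent = trees[v]
        for x, y in edges:
            if x not in parent or y not in parent:
                continue
            px = _path_to_root(parent, x)  # x .. v
            py = _path_to_root(parent, y)  # y .. v
            # vertex-disjoint except at v → simple cycle
            if set(px[:-1]) & set(py[:-1]):
                continue
            if y in px or x in py:
                continue  # (x,y) is a tree edge of this pair of paths
            cycle = px[::-1] + py[:-1]  # v..x, y..v(exclusive) closed by (x,y)
            key = frozenset(cycle)
            if len(key) != len(cycle) or len(cycle) < 3 or key in seen:
                continue
            if max_ring_size is not None and len(cycle) > max_ring_size:
                continue
            seen.add(key)
            bits = 0
            n = len(cycle)
            ok = True
            for k in range(n):
                e = tuple(sorted((cycle[k], cycle[(k + 1) % n])))
                if e not in edge_bit:
                    ok = False
                    break
                bits ^= edge_bit[e]
            if ok:
                candidates.append((n, tuple(cycle), bits))

    candidates.sort(key=lambda c: (c[0], tuple(sorted(
        tuple(sorted((c[1][k], c[1][(k + 1) % c[0]]))) for k in range(c[0])
    ))))

    # Greedy GF(2) independence via incremental Gaussian elimination.
    pivots: list[int] = []
    basis: list[Ring] = []
    for _n, atoms, bits in candidates:
        v = bits
        for p in pivots:
            v = min(v, v ^ p)
        if v:
            pivots.append(v)
            pivots.sort(reverse=True)
            basis.append(Ring(atoms=atoms))
            if len(basis) == target:
                break
    if len(basis) < target:
        log.warning(
            "ring basis incomplete: found %d of %d cycles (ring-size cap?)",
            len(basis), target,
        )
    return basis


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral in degrees for four points (IUPAC convention)."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2  # eclipsed (cis) geometry → 0°
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return math.degrees(math.atan2(y, x))


def classify_ring_planarity(ring: Ring, coords,
                            config: PerceptionConfig | None = None) -> Ring:
    """Annotate a ring with its mean intra-ring torsion and planarity.

    The mean of |dihedral| over all consecutive quadruples around the cycle
    is compared to 7.5° (rings of size 4–5) or 15° (size ≥ 6); 3-rings are
    planar by construction.
    """
    cfg = config or PerceptionConfig()
    coords = np.asarray(coords, dtype=float)
    n = ring.size
    if n == 3:
        ring.mean_torsion = 0.0
        ring.planar = True
        return ring
    torsions = []
    for k in range(n):
        quad = [ring.atoms[(k + m) % n] for m in range(4)]
        torsions.append(abs(dihedral_angle(*(coords[q] for q in quad))))
    ring.mean_torsion = float(np.mean(torsions))
    limit = cfg.planarity_small if n <= 5 else cfg.planarity_large
    ring.planar = ring.mean_torsion < limit
    return ring


def perceive_rings(system: MolecularSystem,
                   config: PerceptionConfig | None = None) -> list[Ring]:
    """Blocks → Horton MCB per block → planarity classification."""
    cfg = config or PerceptionConfig()
    coords = system.coords()
    rings: list[Ring] = []
    for block in find_blocks(system):
        for ring in horton_mcb(block, max_ring_size=cfg.max_ring_size):
            rings.append(classify_ring_planarity(ring, coords, cfg))
    return rings
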