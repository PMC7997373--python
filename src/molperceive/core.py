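"""Central containers: atoms, bonds, and the annotated molecular system."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .chem_data import ElementTable, default_table

__all__ = ["Atom", "Bond", "MolecularSystem"]


@dataclass(frozen=True)
class Atom:
    serial: int  # source-file serial number (1-based for generated systems)
    symbol: str
    xyz: tuple[float, float, float]


@dataclass
class Bond:
    """A perceived bond between atoms ``i`` and ``j`` (0-based indices).

    ``strength`` is the continuous (0, 1] perception score, not an energy.
    ``order`` is the continuous bond order assigned later by the
    distance-based model (default 1 until then).  ``r_e`` is the
    equilibrium length used by the radial strength function.
    """

    i: int
    j: int
    kind: str = "covalent"  # covalent | hydrogen
    strength: float = 1.0
    length: float = 0.0
    r_e: float = 0.0
    order: float = 1.0

    def __post_init__(self):
        if self.i == self.j:
            raise ValueError(f"bond joins atom {self.i} to itself")
        if self.i > self.j:
            self.i, self.j = self.j, self.i

    @property
    def pair(self) -> tuple[int, int]:
        return (self.i, self.j)


class MolecularSystem:
    """Atoms + perceived annotations; the object every stage reads/writes.

    Atom indices are 0-based list positions; source serial numbers are kept
    separately so exports can use file numbering.  Bonds are held as a dict
    keyed by the unordered index pair.
    """

    def __init__(
        self,
        atoms: list[Atom],
        total_charge: int = 0,
        provenance: str = "generated",
        table: ElementTable | None = None,
    ):
        serials = [a.serial for a in atoms]
        if len(set(serials)) != len(serials):
            dup = next(s for s in serials if serials.count(s) > 1)
            raise ValueError(f"duplicate atom serial {dup}")
        coords = np.array([a.xyz for a in atoms], dtype=float).reshape(len(atoms), 3)
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite atom coordinates")
        self.atoms = list(atoms)
        self.total_charge = total_charge
        self.provenance = provenance
        self.table = table or default_table()
        self._bonds: dict[tuple[int, int], Bond] = {}
        self.hybridization: list[str] | None = None  # per-atom labels

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_symbols_coords(
        cls,
        symbols: list[str],
        coords,
        total_charge: int = 0,
        provenance: str = "generated",
        table: ElementTable | None = None,
    ) -> "MolecularSystem":
        atoms = [
            Atom(serial=k + 1, symbol=s, xyz=(float(p[0]), float(p[1]), float(p[2])))
            for k, (s, p) in enumerate(zip(symbols, coords))
        ]
        return cls(atoms, total_charge=total_charge, provenance=provenance, table=table)

    def copy(self) -> "MolecularSystem":
        new = MolecularSystem(
            list(self.atoms), self.total_charge, self.provenance, self.table
        )
        new._bonds = {k: replace(b) for k, b in self._bonds.items()}
        new.hybridization = list(self.hybridization) if self.hybridization else None
        return new

    # -- basic queries ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float)

    def set_coords(self, coords) -> None:
        coords = np.asarray(coords, dtype=float)
        self.atoms = [
            Atom(a.serial, a.symbol, (float(p[0]), float(p[1]), float(p[2])))
            for a, p in zip(self.atoms, coords)
        ]

    def symbols(self) -> list[str]:
        return [a.symbol for a in self.atoms]

    def element(self, i: int):
        return self.table.get(self.atoms[i].symbol)

    def distance(self, i: int, j: int) -> float:
        return float(
            np.linalg.norm(np.subtract(self.atoms[i].xyz, self.atoms[j].xyz))
        )

    # -- bonds -----------------------------------------------------------------

    def add_bond(self, bond: Bond) -> None:
        if not (0 <= bond.i < len(self.atoms) and 0 <= bond.j < len(self.atoms)):
            raise IndexError(f"bond ({bond.i}, {bond.j}) references missing atoms")
        self._bonds[bond.pair] = bond

    def remove_bond(self, i: int, j: int) -> None:
        del self._bonds[(min(i, j), max(i, j))]

    def get_bond(self, i: int, j: int) -> Bond | None:
        return self._bonds.get((min(i, j), max(i, j)))

    def bonds(self, kind: str | None = None) -> list[Bond]:
        bs = sorted(self._bonds.values(), key=lambda b: b.pair)
        if kind is None:
            return bs
        return [b for b in bs if b.kind == kind]

    def clear_bonds(self, kind: str | None = None) -> None:
        if kind is None:
            self._bonds.clear()
        else:
            self._bonds = {k: b for k, b in self._bonds.items() if b.kind != kind}

    def neighbors(self, i: int, kind: str = "covalent") -> list[int]:
        out = []
        for b in self._bonds.values():
            if b.kind != kind:
                continue
            if b.i == i:
                out.append(b.j)
            elif b.j == i:
                out.append(b.i)
        return sorted(out)

    def coordination(self, i: int) -> int:
        return len(self.neighbors(i, "covalent"))

    def covalent_graph(self):
        """The covalent topology as a networkx Graph over atom indices."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(len(self.atoms)))
        g.add_edges_from(b.pair for b in self.bonds("covalent"))
        return g
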