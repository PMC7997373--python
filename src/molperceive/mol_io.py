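"""Structure I/O.

Readers: XYZ, PDB (through gemmi), MOL v3000.  Writers: multi-model XYZ
with ``key=value`` comment-line annotations, MOL2, Gaussian cube, and the
two-column bridge-atom serial list consumed by torsion-parameter tools.

Distances are Å everywhere except inside cube files, which follow the
Gaussian convention of Bohr (conversion factor 0.52917721067 Å/Bohr).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .chem_data import UnknownElementError, default_table
from .core import Atom, Bond, MolecularSystem

__all__ = [
    "FormatError",
    "read_structure",
    "read_multimodel_xyz",
    "write_xyz",
    "write_multimodel_xyz",
    "write_cube",
    "write_mol2",
    "write_hteq_inputs",
    "ANGSTROM_PER_BOHR",
]

ANGSTROM_PER_BOHR = 0.52917721067


class FormatError(ValueError):
    """A structure file violates its format; message names the line."""


_EXT_FORMAT = {".xyz": "xyz", ".pdb": "pdb", ".ent": "pdb", ".mol": "molv3000"}


def read_structure(path: str | Path, fmt: str = "auto") -> MolecularSystem:
    """Read one molecular system from an XYZ, PDB, or MOL v3000 file."""
    path = Path(path)
    if fmt == "auto":
        fmt = _EXT_FORMAT.get(path.suffix.lower())
        if fmt is None:
            raise FormatError(f"cannot infer format from extension of {path.name!r}")
    if fmt == "xyz":
        return _read_xyz(path)
    if fmt == "pdb":
        return _read_pdb(path)
    if fmt == "molv3000":
        return _read_molv3000(path)
    raise ValueError(f"unsupported format {fmt!r}")


# ---------------------------------------------------------------------------
# XYZ

def _parse_xyz_block(lines: list[str], start: int, path: Path):
    """Parse one XYZ frame starting at ``lines[start]``; returns
    (system, comment, next_index)."""
    table = default_table()
    try:
        natoms = int(lines[start].split()[0])
    except (ValueError, IndexError):
        raise FormatError(
            f"{path.name}:{start + 1}: expected an atom count, got {lines[start]!r}"
        ) from None
    if start + 1 >= len(lines):
        raise FormatError(f"{path.name}:{start + 1}: missing comment line")
    comment = lines[start + 1].rstrip("\n")
    atoms = []
    for k in range(natoms):
        ln = start + 2 + k
        if ln >= len(lines):
            raise FormatError(f"{path.name}:{ln + 1}: truncated file, expected {natoms} atoms")
        parts = lines[ln].split()
        if len(parts) < 4:
            raise FormatError(f"{path.name}:{ln + 1}: malformed atom line {lines[ln]!r}")
        sym = table.normalize_symbol(parts[0])
        try:
            x, y, z = (float(v) for v in parts[1:4])
        except ValueError:
            raise FormatError(f"{path.name}:{ln + 1}: bad coordinates {lines[ln]!r}") from None
        atoms.append(Atom(serial=k + 1, symbol=sym, xyz=(x, y, z)))
    return atoms, comment, start + 2 + natoms


def _read_xyz(path: Path) -> MolecularSystem:
    lines = path.read_text().splitlines()
    if not lines:
        raise FormatError(f"{path.name}:1: empty file")
    atoms, _comment, _next = _parse_xyz_block(lines, 0, path)
    return MolecularSystem(atoms, provenance=f"xyz:{path.name}")


def read_multimodel_xyz(path: str | Path) -> list[tuple[MolecularSystem, dict[str, float]]]:
    """Read every frame of a multi-model XYZ; annotations are parsed back
    from ``key=value`` tokens on the comment line."""
    path = Path(path)
    lines = path.read_text().splitlines()
    frames = []
    pos = 0
    while pos < len(lines) and lines[pos].strip():
        atoms, comment, pos = _parse_xyz_block(lines, pos, path)
        ann: dict[str, float] = {}
        for tok in comment.split():
            if "=" in tok:
                k, v = tok.split("=", 1)
                try:
                    ann[k] = float(v)
                except ValueError:
                    pass
        frames.append(
            (MolecularSystem(atoms, provenance=f"xyz:{path.name}"), ann)
        )
    return frames


def write_xyz(system: MolecularSystem, path: str | Path, comment: str = "") -> None:
    write_multimodel_xyz([(system, {})], path, comments=[comment])


def write_multimodel_xyz(
    frames: list[tuple[MolecularSystem, Mapping[str, float]]],
    path: str | Path,
    comments: list[str] | None = None,
) -> None:
    """Write frames as concatenated XYZ blocks.

    Annotations land on each frame's comment line as ``key=value`` pairs
    with fixed 6-decimal formatting, so downstream viewers (and
    :func:`read_multimodel_xyz`) can recover them.
    """
    if not frames:
        raise ValueError("no frames to write")
    n0 = frames[0][0].n_atoms
    for sys_k, _ in frames:
        if sys_k.n_atoms != n0:
            raise ValueError(
                f"inconsistent atom counts across frames: {sys_k.n_atoms} != {n0}"
            )
    out = []
    for k, (system, ann) in enumerate(frames):
        base = comments[k] if comments else ""
        tokens = [base] if base else []
        tokens += [f"{key}={float(val):.6f}" for key, val in ann.items()]
        out.append(str(system.n_atoms))
        out.append(" ".join(tokens))
        for a in system.atoms:
            out.append(f"{a.symbol:<3s} {a.xyz[0]:15.6f} {a.xyz[1]:15.6f} {a.xyz[2]:15.6f}")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# PDB (gemmi does the column parsing and element inference)

def _read_pdb(path: Path) -> MolecularSystem:
    import gemmi

    table = default_table()
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"{path.name}: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"{path.name}: no models found")
    st.setup_entities()
    atoms = []
    seen: set[int] = set()
    model = st[0]
    for chain in model:
        for residue in chain:
            for atom in residue:
                if atom.altloc not in ("", "\0", "A"):
                    continue  # keep the first alternate location only
                serial = atom.serial
                if serial in seen:
                    raise FormatError(
                        f"{path.name}: duplicate atom serial {serial}"
                    )
                seen.add(serial)
                sym = atom.element.name
                if sym not in table:
                    raise UnknownElementError(sym)
                atoms.append(
                    Atom(
                        serial=serial,
                        symbol=table.normalize_symbol(sym),
                        xyz=(atom.pos.x, atom.pos.y, atom.pos.z),
                    )
                )
    if not atoms:
        raise FormatError(f"{path.name}: no ATOM/HETATM records")
    return MolecularSystem(atoms, provenance=f"pdb:{path.name}")


# ---------------------------------------------------------------------------
# MOL v3000

def _read_molv3000(path: Path) -> MolecularSystem:
    table = default_table()
    lines = path.read_text().splitlines()
    try:
        begin_atom = next(i for i, l in enumerate(lines) if "V30 BEGIN ATOM" in l)
    except StopIteration:
        raise FormatError(f"{path.name}: missing 'M  V30 BEGIN ATOM' block") from None

    atoms = []
    i = begin_atom + 1
    while i < len(lines) and "V30 END ATOM" not in lines[i]:
        parts = lines[i].split()
        # M V30 index symbol x y z aamap
        if len(parts) < 7 or parts[0] != "M" or parts[1] != "V30":
            raise FormatError(f"{path.name}:{i + 1}: malformed V30 atom line {lines[i]!r}")
        try:
            serial = int(parts[2])
            sym = table.normalize_symbol(parts[3])
            x, y, z = float(parts[4]), float(parts[5]), float(parts[6])
        except ValueError:
            raise FormatError(f"{path.name}:{i + 1}: bad atom record {lines[i]!r}") from None
        atoms.append(Atom(serial=serial, symbol=sym, xyz=(x, y, z)))
        i += 1
    if i >= len(lines):
        raise FormatError(f"{path.name}: missing 'M  V30 END ATOM'")

    system = MolecularSystem(atoms, provenance=f"molv3000:{path.name}")
    index_of = {a.serial: k for k, a in enumerate(system.atoms)}

    bond_starts = [i for i, l in enumerate(lines) if "V30 BEGIN BOND" in l]
    if bond_starts:
        i = bond_starts[0] + 1
        while i < len(lines) and "V30 END BOND" not in lines[i]:
            parts = lines[i].split()
            if len(parts) < 6:
                raise FormatError(f"{path.name}:{i + 1}: malformed V30 bond line {lines[i]!r}")
            try:
                order = int(parts[3])
                a, b = int(parts[4]), int(parts[5])
            except ValueError:
                raise FormatError(f"{path.name}:{i + 1}: bad bond record {lines[i]!r}") from None
            if a not in index_of or b not in index_of:
                raise FormatError(
                    f"{path.name}:{i + 1}: bond references unknown atom serial"
                )
            ia, ib = index_of[a], index_of[b]
            system.add_bond(
                Bond(ia, ib, kind="covalent", strength=1.0,
                     length=system.distance(ia, ib), order=float(order))
            )
            i += 1
    return system


# ---------------------------------------------------------------------------
# Gaussian cube

def write_cube(grid, system: MolecularSystem, path: str | Path,
               comment: str = "electrostatic potential") -> None:
    """Write a scalar field as a Gaussian cube file.

    Header and positions in Bohr, values in z-fastest order, six per line.
    Axes must be orthogonal (the standard cube readers assume it here).
    """
    axes = np.asarray(grid.axes, dtype=float)
    for a in range(3):
        for b in range(a + 1, 3):
            if abs(float(np.dot(axes[a], axes[b]))) > 1e-9:
                raise ValueError("non-orthogonal grid axes are not supported")
    nx, ny, nz = (int(c) for c in grid.counts)
    if min(nx, ny, nz) < 1:
        raise ValueError("grid counts must be >= 1")
    inv = 1.0 / ANGSTROM_PER_BOHR
    lines = [comment, "generated by molperceive"]
    ox, oy, oz = (float(v) * inv for v in grid.origin)
    lines.append(f"{system.n_atoms:5d}{ox:12.6f}{oy:12.6f}{oz:12.6f}")
    for n, ax in zip((nx, ny, nz), axes):
        vx, vy, vz = (float(v) * inv for v in ax)
        lines.append(f"{n:5d}{vx:12.6f}{vy:12.6f}{vz:12.6f}")
    for a in system.atoms:
        z = system.table.get(a.symbol).Z
        x, y, zc = (float(v) * inv for v in a.xyz)
        lines.append(f"{z:5d}{0.0:12.6f}{x:12.6f}{y:12.6f}{zc:12.6f}")
    vals = np.asarray(grid.values, dtype=float).reshape(nx, ny, nz)
    flat = vals.reshape(-1)  # C order == z fastest
    for start in range(0, flat.size, 6):
        chunk = flat[start:start + 6]
        lines.append("".join(f"{v:13.5E}" for v in chunk))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# MOL2 + HTEQ hand-off

def _mol2_bond_type(order: float) -> str:
    if abs(order - 1.5) <= 0.4:
        return "ar"
    return str(int(min(3, max(1, round(order)))))


def write_mol2(system: MolecularSystem, path: str | Path, name: str = "MOL") -> None:
    """Write a minimal TRIPOS MOL2: atoms, and covalent bonds with orders
    rounded to {1, 2, 3, ar} (orders within 0.4 of 1.5 become aromatic)."""
    bonds = system.bonds("covalent")
    aromatic_atoms = set()
    typed = []
    for b in bonds:
        t = _mol2_bond_type(b.order)
        typed.append((b, t))
        if t == "ar":
            aromatic_atoms.update(b.pair)
    lines = [
        "@<TRIPOS>MOLECULE",
        name,
        f"{system.n_atoms} {len(bonds)} 0 0 0",
        "SMALL",
        "NO_CHARGES",
        "",
        "@<TRIPOS>ATOM",
    ]
    for k, a in enumerate(system.atoms):
        atype = f"{a.symbol}.ar" if k in aromatic_atoms else a.symbol
        lines.append(
            f"{k + 1:>6d} {a.symbol}{k + 1:<4d} {a.xyz[0]:>10.4f} {a.xyz[1]:>10.4f}"
            f" {a.xyz[2]:>10.4f} {atype:<6s} 1 UNL 0.0000"
        )
    lines.append("@<TRIPOS>BOND")
    for n, (b, t) in enumerate(typed, 1):
        lines.append(f"{n:>6d} {b.i + 1:>6d} {b.j + 1:>6d} {t:>4s}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_hteq_inputs(fragment, bridge, outdir: str | Path,
                      basename: str = "bridge") -> tuple[Path, Path]:
    """Write the MOL2 + bridge-serial pair files a torsion-parameter tool
    (HTEQ-style) expects.  ``fragment`` is a cut subsystem; ``bridge`` must
    reference atoms present in it (fragment-local indices)."""
    system = fragment.system if hasattr(fragment, "system") else fragment
    n = system.n_atoms
    if not (0 <= bridge.i < n and 0 <= bridge.j < n):
        raise ValueError("bridge atoms are missing from the fragment")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mol2_path = outdir / f"{basename}.mol2"
    serial_path = outdir / f"{basename}_bridge.txt"
    write_mol2(system, mol2_path, name=basename)
    si = system.atoms[bridge.i].serial
    sj = system.atoms[bridge.j].serial
    serial_path.write_text(f"{si} {sj}\n")
    return mol2_path, serial_path
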