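"""End-to-end perception: bonds → rings → hybridization → charges → orders.

The stage order is forced by the data dependencies: hybridization needs
ring planarity, PEOE charges need hybridization-resolved parameters, and
valence filtering needs both the raw orders and the hybridization-based
exemptions.
"""

from __future__ import annotations

from . import __version__
from .bond_orders import assign_bond_orders
from .bond_perception import perceive_covalent_bonds, perceive_hydrogen_bonds
from .charges import gasteiger_charges, qeq_charges
from .config import PerceptionConfig
from .core import MolecularSystem
from .hybridization import assign_hybridization
from .ring_perception import perceive_rings

__all__ = ["run_pipeline"]


def run_pipeline(
    system: MolecularSystem,
    config: PerceptionConfig | None = None,
    hbonds: bool = True,
    charge_method: str = "gasteiger",
    total_charge: float | None = None,
) -> dict:
    """Run every perception stage; returns one JSON-serializable document."""
    cfg = config or PerceptionConfig()
    perceive_covalent_bonds(system, cfg)
    if hbonds:
        perceive_hydrogen_bonds(system, cfg)
    rings = perceive_rings(system, cfg)
    labels = assign_hybridization(system, rings, cfg)
    if charge_method == "gasteiger":
        charge_set = gasteiger_charges(system, total_charge, config=cfg)
    elif charge_method == "qeq":
        charge_set = qeq_charges(system, total_charge, config=cfg)
    else:
        raise ValueError(f"unknown charge method {charge_method!r}")
    assignment = assign_bond_orders(system, cfg)

    serial = [a.serial for a in system.atoms]
    doc = {
        "tool": "molperceive",
        "version": __version__,
        "provenance": system.provenance,
        "config": cfg.to_dict(),
        "n_atoms": system.n_atoms,
        "atoms": [
            {
                "serial": a.serial,
                "symbol": a.symbol,
                "xyz": [round(v, 6) for v in a.xyz],
                "hybridization": labels[k],
                "charge": round(float(charge_set.charges[k]), 6),
            }
            for k, a in enumerate(system.atoms)
        ],
        "bonds": [
            {
                "serial_i": serial[b.i],
                "serial_j": serial[b.j],
                "kind": b.kind,
                "length": round(b.length, 6),
                "strength": round(b.strength, 6),
                "order": round(b.order, 6) if b.kind == "covalent" else None,
            }
            for b in system.bonds()
        ],
        "rings": [
            {
                "size": r.size,
                "planar": r.planar,
                "mean_torsion": round(r.mean_torsion, 4),
                "serials": [serial[i] for i in r.atoms],
            }
            for r in rings
        ],
        "charges": {
            "method": charge_set.method,
            "total": charge_set.total,
            "values": [round(float(q), 6) for q in charge_set.charges],
        },
        "bond_orders": {
            "feasible": assignment.feasible,
            "residual": assignment.residual,
            "targets": {str(serial[i]): t for i, t in sorted(assignment.targets.items())},
        },
    }
    return doc
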