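"""Run configuration: every tunable threshold, with its default, in one place.

A flat ``key=value`` text file (or any mapping) can override defaults;
unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

__all__ = ["PerceptionConfig"]


@dataclass
class PerceptionConfig:
    # covalent bond perception (Å / dimensionless)
    min_dist: float = 0.4
    tolerance: float = 0.4
    strength_threshold: float = 0.4
    c_en: float = 0.09  # Å per electronegativity unit (Schomaker–Stevenson)

    # hydrogen bonds: donor–acceptor heavy-atom reference distances (Å)
    hbond_r_e_oo: float = 2.9
    hbond_r_e_on: float = 3.0
    hbond_r_e_nn: float = 3.1
    hbond_theta_e: float = 180.0  # ideal donor–H–acceptor angle, degrees
    hbond_theta_tol: float = 60.0  # angular tolerance (strength = threshold there)
    hbond_threshold: float = 0.4

    # hybridization heuristic cutoffs (degrees, midpoints of ideal geometries)
    sp_cutoff: float = 155.0
    sp2_cutoff: float = 115.0
    planarity_small: float = 7.5  # mean-torsion limit, rings of size 4–5
    planarity_large: float = 15.0  # rings of size ≥ 6
    terminal_slack: float = 0.1  # Å added to radii sums in terminal-atom tests
    metals: tuple[str, ...] = (
        "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
        "Mo", "Ru", "Rh", "Pd", "Ag", "Cd", "W", "Re", "Os", "Ir", "Pt", "Au", "Hg",
    )

    # ring perception
    max_ring_size: int = 20

    # charges
    peoe_n_iter: int = 6
    qeq_shielding: str = "shielded"  # shielded | plain

    # bond orders
    bo_min: float = 0.1  # clamp floor for raw distance-based orders
    bo_max_flag: float = 4.0  # raw orders above this are flagged
    constrain_terminal: bool = False  # exempt non-H terminal atoms by default

    # biaryl / torsion energetics
    cut_depth: int = 4
    v2_alpha: float = 1.0  # kcal/mol per electronegativity unit (uncalibrated)
    v2_beta: float = 0.0
    clash_dist: float = 0.5  # Å; closer non-bonded pairs flag a clash
    clash_energy: float = 1.0e6  # kcal/mol sentinel for clashed scan points

    # grids
    esp_units: str = "e_per_angstrom"  # e_per_angstrom | hartree_e
    scan_step: float = 10.0  # degrees

    def replace(self, **kw) -> "PerceptionConfig":
        d = asdict(self)
        d.update(kw)
        return PerceptionConfig(**{k: v for k, v in d.items()})

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_file(cls, path: str | Path) -> "PerceptionConfig":
        """Parse a flat key=value file; '#' starts a comment."""
        known = {f.name: f for f in fields(cls)}
        kw = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value, got {raw!r}")
            key, value = (s.strip() for s in line.split("=", 1))
            key = key.replace(".", "_")
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            f = known[key]
            if f.type in ("float", float):
                kw[key] = float(value)
            elif f.type in ("int", int):
                kw[key] = int(value)
            elif f.type in ("bool", bool):
                kw[key] = value.lower() in ("1", "true", "yes", "on")
            elif f.name == "metals":
                kw[key] = tuple(s.strip() for s in value.split(",") if s.strip())
            else:
                kw[key] = value
        return cls(**kw)
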