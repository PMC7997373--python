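"""Continuous distance-based bond orders with valence-constrained filtering.

Per element, the Pyykkö single/double/triple covalent radii are fitted with
the log-linear law r(BO) = a − b·ln(BO).  Because each atom contributes its
r(BO) to the bond length additively, the law inverts in closed form for any
element pair:

    BO(d) = exp((a_A + a_B − d) / (b_A + b_B))

so BO = 1 exactly at d = a_A + a_B and the order decays smoothly with
distance.  Raw orders inherit every Å of coordinate error, so a filtering
step projects them onto the affine space where each constrained atom's
incident orders sum to its chosen valence: minimise ‖x − x₀‖² subject to
A·x = v, a Lagrange-multiplier problem solved through its KKT system.
Negative projected orders are clamped to zero once and the projection
re-solved with those bonds fixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .chem_data import ElementRecord, ElementTable, ParameterizationError
from .config import PerceptionConfig
from .core import MolecularSystem

__all__ = [
    "BOCurve",
    "BOAssignment",
    "fit_bo_curve",
    "default_slope",
    "distance_bond_order",
    "assign_raw_orders",
    "choose_valences",
    "filter_bond_orders",
    "assign_bond_orders",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BOCurve:
    """Per-element fit r(BO) = a − b·ln(BO); a, b in Å."""

    element: str
    a: float
    b: float
    n_points: int
    residual: float = 0.0


@dataclass
class BOAssignment:
    """Filtered bond orders plus the per-atom valence targets used."""

    orders: np.ndarray  # one per bond, aligned with the input order
    targets: dict[int, float]  # constrained atom -> valence
    feasible: bool
    residual: float
    diagnostics: list[str] = field(default_factory=list)


def default_slope(table: ElementTable) -> float:
    """Radii-weighted mean slope over elements with ≥ 2 fitted points;
    the fallback b for single-radius elements."""
    slopes, weights = [], []
    for sym in table.symbols():
        rec = table.get(sym)
        pts = rec.pyykko_points()
        if len(pts) >= 2:
            curve = _fit(rec, None)
            slopes.append(curve.b)
            weights.append(rec.r_pyykko_s)
    return float(np.average(slopes, weights=weights))


def _fit(rec: ElementRecord, fallback_slope: float | None) -> BOCurve:
    pts = rec.pyykko_points()
    if not pts:
        raise ParameterizationError(f"no covalent radii for element {rec.symbol}")
    if len(pts) == 1:
        if fallback_slope is None:
            raise ParameterizationError(
                f"element {rec.symbol} has one radius and no fallback slope"
            )
        return BOCurve(rec.symbol, pts[0][1], fallback_slope, 1)
    x = np.log([bo for bo, _ in pts])
    y = np.array([r for _, r in pts])
    design = np.column_stack([np.ones_like(x), -x])
    (a, b), res, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = float(np.sqrt(res[0])) if res.size else 0.0
    return BOCurve(rec.symbol, float(a), float(b), len(pts), resid)


_CURVE_CACHE: dict[tuple[int, str], BOCurve] = {}


def fit_bo_curve(element: str | ElementRecord, table: ElementTable | None = None) -> BOCurve:
    """Log-linear radius-vs-order fit for one element (cached per table)."""
    if table is None:
        from .chem_data import default_table

        table = default_table()
    rec = table.get(element) if isinstance(element, str) else element
    key = (id(table), rec.symbol)
    if key not in _CURVE_CACHE:
        _CURVE_CACHE[key] = _fit(rec, default_slope(table))
    return _CURVE_CACHE[key]


def distance_bond_order(
    d: float,
    curve_a: BOCurve,
    curve_b: BOCurve,
    clamp: bool = True,
    bo_min: float = 0.1,
    bo_max_flag: float = 4.0,
) -> float:
    """Closed-form continuous bond order for a bond of length d (Å)."""
    if d <= 0:
        raise ValueError(f"distance must be positive, got {d}")
    denom = curve_a.b + curve_b.b
    if denom <= 0:
        raise ValueError(
            f"degenerate curves for {curve_a.element}-{curve_b.element}: zero slope sum"
        )
    raw = float(np.exp((curve_a.a + curve_b.a - d) / denom))
    if not clamp:
        return raw
    if raw < bo_min:
        log.warning("bond order %.3g below %.2g for %s-%s at %.3f Å, clamped",
                    raw, bo_min, curve_a.element, curve_b.element, d)
        return bo_min
    if raw > bo_max_flag:
        log.warning("suspicious bond order %.3g (> %.2g) for %s-%s at %.3f Å",
                    raw, bo_max_flag, curve_a.element, curve_b.element, d)
    return raw


def assign_raw_orders(system: MolecularSystem,
                      config: PerceptionConfig | None = None) -> np.ndarray:
    """Distance-based order for every covalent bond (also stored on bonds)."""
    cfg = config or PerceptionConfig()
    orders = []
    for bond in system.bonds("covalent"):
        ca = fit_bo_curve(system.atoms[bond.i].symbol, system.table)
        cb = fit_bo_curve(system.atoms[bond.j].symbol, system.table)
        bo = distance_bond_order(system.distance(bond.i, bond.j), ca, cb,
                                 bo_min=cfg.bo_min, bo_max_flag=cfg.bo_max_flag)
        bond.order = bo
        orders.append(bo)
    return np.array(orders)


def choose_valences(system: MolecularSystem, raw_orders: Sequence[float],
                    config: PerceptionConfig | None = None) -> dict[int, float]:
    """Pick each constrained atom's valence target.

    Hydrogens are fixed at 1; atoms with several allowed valences take the
    one nearest their raw order sum (ties resolved downward).  Terminal
    non-hydrogen atoms, metal-labelled atoms, and atoms of unknown
    hybridization are exempt (their valence is genuinely ambiguous).
    """
    cfg = config or PerceptionConfig()
    bonds = system.bonds("covalent")
    sums = np.zeros(system.n_atoms)
    degree = np.zeros(system.n_atoms, dtype=int)
    for bond, bo in zip(bonds, raw_orders):
        sums[bond.i] += bo
        sums[bond.j] += bo
        degree[bond.i] += 1
        degree[bond.j] += 1
    hyb = system.hybridization or ["unknown"] * system.n_atoms

    targets: dict[int, float] = {}
    for i, atom in enumerate(system.atoms):
        if degree[i] == 0:
            continue
        if atom.symbol == "H":
            targets[i] = 1.0
            continue
        if hyb[i] in ("metal", "unknown"):
            continue
        if degree[i] == 1 and not cfg.constrain_terminal:
            continue
        allowed = system.table.get(atom.symbol).valences
        if not allowed:
            continue
        # nearest allowed valence; ties broken toward the smaller valence
        targets[i] = float(min(allowed, key=lambda v: (abs(v - sums[i]), v)))
    return targets


def _kkt_project(x0: np.ndarray, A: np.ndarray, v: np.ndarray) -> np.ndarray:
    """argmin ‖x − x₀‖² s.t. A·x = v via the normal KKT equations; the
    minimum-norm multiplier handles rank deficiency."""
    lam, *_ = np.linalg.lstsq(A @ A.T, v - A @ x0, rcond=None)
    return x0 + A.T @ lam


def filter_bond_orders(
    raw_orders: Sequence[float],
    incidence: Mapping[int, Sequence[int]],
    targets: Mapping[int, float],
) -> BOAssignment:
    """Project raw orders onto the valence-constraint subspace.

    ``incidence`` maps each atom to the bond positions incident on it;
    only atoms present in ``targets`` constrain the projection.
    """
    x0 = np.asarray(raw_orders, dtype=float)
    atoms = sorted(targets)
    if not atoms:
        return BOAssignment(x0.copy(), {}, True, 0.0)
    A = np.zeros((len(atoms), x0.size))
    for row, atom in enumerate(atoms):
        for b in incidence.get(atom, ()):
            A[row, b] = 1.0
    v = np.array([targets[a] for a in atoms], dtype=float)

    x = _kkt_project(x0, A, v)
    clamped = x < -1e-12
    if np.any(clamped):
        # fix negative orders at zero, re-project the free bonds once
        free = ~clamped
        x = np.zeros_like(x0)
        x[free] = _kkt_project(x0[free], A[:, free], v)

    resid = float(np.max(np.abs(A @ x - v))) if atoms else 0.0
    diagnostics: list[str] = []
    if resid > 1e-6:
        order = np.argsort(np.abs(A @ x - v))[::-1][:5]
        for k in order:
            diagnostics.append(
                f"atom {atoms[k]}: target {v[k]:.3f}, got {(A @ x)[k]:.3f}"
            )
        return BOAssignment(x0.copy(), dict(targets), False, resid, diagnostics)
    return BOAssignment(x, dict(targets), resid <= 1e-8, resid, diagnostics)


def assign_bond_orders(system: MolecularSystem,
                       config: PerceptionConfig | None = None) -> BOAssignment:
    """Raw distance-based orders → valence targets → filtered orders.

    Stores the filtered orders back on the system's bonds.  Changing orders
    never alters the perceived bond set: strength and order are decoupled.
    """
    cfg = config or PerceptionConfig()
    bonds = system.bonds("covalent")
    raw = assign_raw_orders(system, cfg)
    targets = choose_valences(system, raw, cfg)
    incidence: dict[int, list[int]] = {}
    for k, bond in enumerate(bonds):
        incidence.setdefault(bond.i, []).append(k)
        incidence.setdefault(bond.j, []).append(k)
    assignment = filter_bond_orders(raw, incidence, targets)
    for bond, bo in zip(bonds, assignment.orders):
        bond.order = float(bo)
    return assignment
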