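"""Partial atomic charges: Gasteiger PEOE and QEq charge equilibration.

The two models are deliberately complementary: PEOE sees only the covalent
topology (geometry-free), QEq sees only positions and element parameters
(topology-free).  Both conserve the requested total charge exactly.

PEOE: each atom's electronegativity is a quadratic in its charge,
χ_i(q) = a + b·q + c·q², with hybridization-dependent coefficients.  Each
iteration k transfers charge across every bond from the less to the more
electronegative atom, Δq = (χ_j − χ_i)/χ⁺ · (1/2)^k, normalised by the
donor's cation electronegativity χ⁺ = χ(+1) (the conventional 20.02 for
hydrogen).  The damping factor makes the series converge geometrically.

QEq: charges minimise E(q) = Σ χ⁰_i q_i + ½ Σ_ij J_ij q_i q_j subject to
Σ q_i = Q, i.e. all effective electronegativities equal a common chemical
potential.  This is one KKT linear solve.  The off-diagonal J_ij is the
Coulomb interaction 14.4/r (eV·Å), optionally shielded as
14.4/sqrt(r² + r₀²) with r₀ = 2·14.4/(J_ii + J_jj), which tends to the
correct self-interaction mean at r → 0 instead of diverging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem_data import ParameterizationError
from .config import PerceptionConfig
from .core import MolecularSystem

__all__ = ["ChargeSet", "gasteiger_charges", "qeq_charges"]

COULOMB_EV_ANGSTROM = 14.399645  # e²/(4πε₀) in eV·Å
H_CATION_CHI = 20.02  # conventional PEOE cation electronegativity of H


@dataclass
class ChargeSet:
    method: str  # gasteiger | qeq
    charges: np.ndarray  # elementary charges, one per atom
    total: float
    iterations_or_residual: float

    def __post_init__(self):
        self.charges = np.asarray(self.charges, dtype=float)
        if not np.all(np.isfinite(self.charges)):
            raise ValueError("non-finite charges")


# PEOE parameter lookup treats `unknown` like an sp3 environment for the
# elements whose coefficients are state-independent anyway.
_HYB_FALLBACK = {"unknown": "sp3", "metal": "sp3", "sp": "sp"}


def _peoe_coeffs(system: MolecularSystem, i: int) -> tuple[float, float, float]:
    sym = system.atoms[i].symbol
    hyb = (system.hybridization or ["unknown"] * system.n_atoms)[i]
    rec = system.table.get(sym)
    if not rec.peoe_params:
        raise ParameterizationError(f"no PEOE parameters for element {sym}")
    try:
        return rec.peoe_coefficients(hyb)
    except ParameterizationError:
        return rec.peoe_coefficients(_HYB_FALLBACK.get(hyb, hyb))


def gasteiger_charges(
    system: MolecularSystem,
    total_charge: float | None = None,
    n_iter: int | None = None,
    config: PerceptionConfig | None = None,
) -> ChargeSet:
    """Iterative partial equalization of orbital electronegativity."""
    cfg = config or PerceptionConfig()
    n_iter = n_iter if n_iter is not None else cfg.peoe_n_iter
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    total = float(system.total_charge if total_charge is None else total_charge)
    n = system.n_atoms
    coeffs = [_peoe_coeffs(system, i) for i in range(n)]

    def chi_plus(i: int) -> float:
        if system.atoms[i].symbol == "H":
            return H_CATION_CHI
        a, b, c = coeffs[i]
        return a + b + c  # χ at q = +1

    q = np.full(n, total / n)  # seed: net charge spread uniformly
    bonds = [b.pair for b in system.bonds("covalent")]
    for k in range(1, n_iter + 1):
        chi = np.array([a + b * qi + c * qi * qi for (a, b, c), qi in zip(coeffs, q)])
        damp = 0.5**k
        dq = np.zeros(n)
        for i, j in bonds:
            if chi[j] > chi[i]:
                t = (chi[j] - chi[i]) / chi_plus(i) * damp
                dq[i] += t
                dq[j] -= t
            elif chi[i] > chi[j]:
                t = (chi[i] - chi[j]) / chi_plus(j) * damp
                dq[j] += t
                dq[i] -= t
        q = q + dq
    return ChargeSet("gasteiger", q, total, float(n_iter))


def _qeq_offdiagonal(r: np.ndarray, hardness: np.ndarray, mode: str) -> np.ndarray:
    with np.errstate(divide="ignore"):
        if mode == "plain":
            j = COULOMB_EV_ANGSTROM / r
        elif mode == "shielded":
            r0 = 2.0 * COULOMB_EV_ANGSTROM / (hardness[:, None] + hardness[None, :])
            j = COULOMB_EV_ANGSTROM / np.sqrt(r**2 + r0**2)
        else:
            raise ValueError(f"unknown qeq shielding mode {mode!r}")
    return j


def qeq_charges(
    system: MolecularSystem,
    total_charge: float | None = None,
    config: PerceptionConfig | None = None,
) -> ChargeSet:
    """Charge equilibration as a single constrained linear solve."""
    cfg = config or PerceptionConfig()
    total = float(system.total_charge if total_charge is None else total_charge)
    n = system.n_atoms
    chi0 = np.empty(n)
    hard = np.empty(n)
    for i, atom in enumerate(system.atoms):
        params = system.table.get(atom.symbol).qeq_params
        if params is None:
            raise ParameterizationError(f"no QEq parameters for element {atom.symbol}")
        chi0[i], hard[i] = params
    if n == 1:
        return ChargeSet("qeq", np.array([total]), total, 0.0)

    coords = system.coords()
    diff = coords[:, None, :] - coords[None, :, :]
    r = np.linalg.norm(diff, axis=-1)
    close = (r < 1e-8) & ~np.eye(n, dtype=bool)
    if np.any(close):
        i, j = np.argwhere(close)[0]
        raise np.linalg.LinAlgError(
            f"QEq system singular: atoms {system.atoms[i].serial} and "
            f"{system.atoms[j].serial} coincide"
        )
    J = _qeq_offdiagonal(r, hard, cfg.qeq_shielding)
    np.fill_diagonal(J, hard)

    # KKT system: [J  1; 1ᵀ 0] [q; -μ] = [-χ⁰; Q]
    M = np.zeros((n + 1, n + 1))
    M[:n, :n] = J
    M[:n, n] = 1.0
    M[n, :n] = 1.0
    rhs = np.concatenate([-chi0, [total]])
    sol = np.linalg.solve(M, rhs)
    q = sol[:n]
    resid = np.linalg.norm(M @ sol - rhs) / max(np.linalg.norm(rhs), 1.0)
    return ChargeSet("qeq", q, total, float(resid))
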