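"""Embedded element tables: the single source of physical constants.

Every perception stage reads its per-element constants (covalent radii,
Pyykkö multiple-bond radii, electronegativities, allowed valences, PEOE and
QEq charge parameters, UFF nonbonded parameters) from the plain-text tables
shipped under ``molperceive/data/``.  The tables are documented column by
column in the files themselves; :class:`ElementTable` is the only code path
that reads them, so swapping a scale (e.g. a different electronegativity
table) is a data change, not a code change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

__all__ = [
    "ElementRecord",
    "ElementTable",
    "UnknownElementError",
    "ParameterizationError",
    "get_element",
    "electronegativity_difference",
    "default_table",
]


class UnknownElementError(KeyError):
    """Raised for a symbol with no entry in the element tables."""

    def __init__(self, symbol: str):
        super().__init__(symbol)
        self.symbol = symbol

    def __str__(self) -> str:  # KeyError quotes its arg; we want prose
        return f"unknown element: {self.symbol!r}"


class ParameterizationError(ValueError):
    """An element lacks the parameters a stage needs (fail loudly)."""


@dataclass(frozen=True)
class ElementRecord:
    """Per-element physical constants.

    Radii are in Å, electronegativity on the configured (default Pauling)
    scale, QEq parameters in eV, UFF parameters in (Å, kcal/mol).
    ``r_pyykko_d`` / ``r_pyykko_t`` are ``None`` where the tabulation has no
    double/triple-bond radius (or where including it would break the
    monotonic ordering the bond-order fit relies on).
    """

    symbol: str
    Z: int
    r_cov: float
    r_pyykko_s: float
    r_pyykko_d: float | None
    r_pyykko_t: float | None
    chi: float
    valences: tuple[int, ...]
    max_coordination: int
    peoe_params: Mapping[str, tuple[float, float, float]] = field(default_factory=dict)
    qeq_params: tuple[float, float] | None = None  # (chi0, hardness), eV
    uff_params: tuple[float, float] | None = None  # (x, d): Å, kcal/mol

    def pyykko_points(self) -> list[tuple[float, float]]:
        """(bond order, radius) pairs available for the log-linear fit."""
        pts = [(1.0, self.r_pyykko_s)]
        if self.r_pyykko_d is not None:
            pts.append((2.0, self.r_pyykko_d))
        if self.r_pyykko_t is not None:
            pts.append((3.0, self.r_pyykko_t))
        return pts

    def peoe_coefficients(self, hyb: str) -> tuple[float, float, float]:
        """PEOE (a, b, c) for a hybridization state, falling back to '*'."""
        if hyb in self.peoe_params:
            return self.peoe_params[hyb]
        if "*" in self.peoe_params:
            return self.peoe_params["*"]
        raise ParameterizationError(
            f"no PEOE parameters for element {self.symbol} in state {hyb!r}"
        )


def _read_rows(name: str) -> list[list[str]]:
    text = resources.files("molperceive.data").joinpath(name).read_text()
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows


def _opt(s: str) -> float | None:
    return None if s == "-" else float(s)


class ElementTable:
    """Lookup of :class:`ElementRecord` by case-insensitive symbol.

    ``chi_overrides`` / ``qeq_overrides`` replace individual entries of the
    electronegativity and QEq tables without touching the packaged files.
    """

    def __init__(
        self,
        chi_overrides: Mapping[str, float] | None = None,
        qeq_overrides: Mapping[str, tuple[float, float]] | None = None,
    ):
        chi = {r[0]: float(r[1]) for r in _read_rows("electronegativity.tsv")}
        if chi_overrides:
            chi.update(chi_overrides)
        valences = {
            r[0]: tuple(int(v) for v in r[1].split(",")) for r in _read_rows("valences.tsv")
        }
        qeq = {r[0]: (float(r[1]), float(r[2])) for r in _read_rows("qeq.tsv")}
        if qeq_overrides:
            qeq.update(qeq_overrides)
        uff = {r[0]: (float(r[1]), float(r[2])) for r in _read_rows("uff_vdw.tsv")}
        peoe: dict[str, dict[str, tuple[float, float, float]]] = {}
        for sym, hyb, a, b, c in _read_rows("peoe.tsv"):
            peoe.setdefault(sym, {})[hyb] = (float(a), float(b), float(c))

        self._records: dict[str, ElementRecord] = {}
        for sym, z, r_cov, r_s, r_d, r_t, max_coord in _read_rows("radii.tsv"):
            self._records[sym] = ElementRecord(
                symbol=sym,
                Z=int(z),
                r_cov=float(r_cov),
                r_pyykko_s=float(r_s),
                r_pyykko_d=_opt(r_d),
                r_pyykko_t=_opt(r_t),
                chi=chi[sym],
                valences=valences.get(sym, ()),
                max_coordination=int(max_coord),
                peoe_params=peoe.get(sym, {}),
                qeq_params=qeq.get(sym),
                uff_params=uff.get(sym),
            )
        self._by_lower = {s.lower(): s for s in self._records}

    def get(self, symbol: str) -> ElementRecord:
        key = self._by_lower.get(symbol.strip().lower())
        if key is None:
            raise UnknownElementError(symbol)
        return self._records[key]

    def normalize_symbol(self, symbol: str) -> str:
        return self.get(symbol).symbol

    def __contains__(self, symbol: str) -> bool:
        return symbol.strip().lower() in self._by_lower

    def symbols(self) -> list[str]:
        return list(self._records)

    def chi_difference(self, a: str, b: str) -> float:
        return abs(self.get(a).chi - self.get(b).chi)


_DEFAULT: ElementTable | None = None


def default_table() -> ElementTable:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = ElementTable()
    return _DEFAULT


def get_element(symbol: str) -> ElementRecord:
    """Return the full constant record for an element symbol."""
    return default_table().get(symbol)


def electronegativity_difference(a: str, b: str) -> float:
    """|χ_a − χ_b| on the configured scale; symmetric and ≥ 0."""
    return default_table().chi_difference(a, b)
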