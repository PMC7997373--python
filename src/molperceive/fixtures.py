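"""Reference molecules built from ideal geometries.

Every structure here is generated from textbook bond lengths and angles at
import time — nothing is read from disk — except celecoxib, whose frozen
force-field-optimized conformer is embedded as text (synthetic stand-in
for an experimental geometry; 40 atoms, MMFF94-relaxed).
"""

from __future__ import annotations

import math

import numpy as np

from .core import MolecularSystem

__all__ = ["water", "water_dimer", "methane", "ethane", "benzene",
           "biphenyl", "naphthalene", "cubane_skeleton", "nacl_pair",
           "dinitrogen", "celecoxib"]

_OH = 0.96  # Å
_CH = 1.09
_CC = 1.54
_CC_AR = 1.39
_HOH = 104.5  # degrees


def _system(symbols, coords, **kw) -> MolecularSystem:
    return MolecularSystem.from_symbols_coords(symbols, np.asarray(coords), **kw)


def water(origin=(0.0, 0.0, 0.0)) -> MolecularSystem:
    """H₂O with O–H 0.96 Å and ∠HOH 104.5°, in the xy-plane."""
    half = math.radians(_HOH / 2)
    o = np.asarray(origin, dtype=float)
    coords = [
        o,
        o + [_OH * math.sin(half), _OH * math.cos(half), 0.0],
        o + [-_OH * math.sin(half), _OH * math.cos(half), 0.0],
    ]
    return _system(["O", "H", "H"], coords, provenance="fixture:water")


def water_dimer(r_oo: float = 2.9) -> MolecularSystem:
    """Two waters with a linear O–H···O hydrogen bond at the given O···O
    distance; the acceptor's hydrogens point away from the donor."""
    donor = water()
    d_coords = donor.coords()
    u = d_coords[1] - d_coords[0]  # donor O→H unit vector
    u /= np.linalg.norm(u)
    a_o = d_coords[0] + r_oo * u  # acceptor O on the O–H extension
    w = np.array([-u[1], u[0], 0.0])  # in-plane perpendicular
    half = math.radians(_HOH / 2)
    a_h1 = a_o + _OH * (math.cos(half) * u + math.sin(half) * w)
    a_h2 = a_o + _OH * (math.cos(half) * u - math.sin(half) * w)
    symbols = donor.symbols() + ["O", "H", "H"]
    coords = np.vstack([d_coords, a_o, a_h1, a_h2])
    return _system(symbols, coords, provenance="fixture:water_dimer")


def methane() -> MolecularSystem:
    """CH₄ with ideal tetrahedral H positions at 1.09 Å."""
    t = _CH / math.sqrt(3)
    coords = [
        [0.0, 0.0, 0.0],
        [t, t, t], [t, -t, -t], [-t, t, -t], [-t, -t, t],
    ]
    return _system(["C", "H", "H", "H", "H"], coords, provenance="fixture:methane")


def ethane(eclipsed: bool = False) -> MolecularSystem:
    """C₂H₆, staggered by default."""
    cz = _CC / 2
    theta0 = 0.0 if eclipsed else math.pi / 3
    tetra = math.radians(180.0 - 109.47)  # H tilt from the C–C axis
    coords = [[0.0, 0.0, -cz], [0.0, 0.0, cz]]
    symbols = ["C", "C"]
    for sign, base in ((-1, 0.0), (1, theta0)):
        for k in range(3):
            ang = base + 2 * math.pi * k / 3
            coords.append([
                _CH * math.sin(tetra) * math.cos(ang),
                _CH * math.sin(tetra) * math.sin(ang),
                sign * (cz + _CH * math.cos(tetra)),
            ])
            symbols.append("H")
    return _system(symbols, coords, provenance="fixture:ethane")


def _hexagon(center, radius, z=0.0, phase=0.0):
    return [
        [center[0] + radius * math.cos(phase + k * math.pi / 3),
         center[1] + radius * math.sin(phase + k * math.pi / 3), z]
        for k in range(6)
    ]


def benzene() -> MolecularSystem:
    """Ideal D₆ₕ benzene: C–C 1.39 Å, C–H 1.09 Å, flat in z = 0."""
    cs = _hexagon((0.0, 0.0), _CC_AR)
    hs = _hexagon((0.0, 0.0), _CC_AR + _CH)
    return _system(["C"] * 6 + ["H"] * 6, cs + hs, provenance="fixture:benzene")


def _rotation_matrix(axis, angle):
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    a = math.cos(angle / 2)
    b, c, d = -axis * math.sin(angle / 2)
    return np.array([
        [a*a + b*b - c*c - d*d, 2*(b*c + a*d), 2*(b*d - a*c)],
        [2*(b*c - a*d), a*a + c*c - b*b - d*d, 2*(c*d + a*b)],
        [2*(b*d + a*c), 2*(c*d - a*b), a*a + d*d - b*b - c*c],
    ])


def biphenyl(twist: float = 44.0, r_bridge: float = 1.48) -> MolecularSystem:
    """Two phenyl rings joined by a C–C bridge, ring B twisted about the
    bridge axis by ``twist`` degrees (0 = planar, clash-prone)."""
    half = r_bridge / 2
    symbols, coords = [], []
    for side in (-1, 1):
        center = (side * (half + _CC_AR), 0.0)
        phase = 0.0 if side == -1 else math.pi  # put one vertex on the bridge
        ring = np.array(_hexagon(center, _CC_AR, phase=phase))
        hpos = np.array(_hexagon(center, _CC_AR + _CH, phase=phase))
        if side == 1:
            rot = _rotation_matrix([1.0, 0.0, 0.0], math.radians(twist))
            ring = ring @ rot.T
            hpos = hpos @ rot.T
        symbols += ["C"] * 6
        coords += list(ring)
        # hydrogen on every ring carbon except the bridge vertex (k = 0)
        symbols += ["H"] * 5
        coords += list(hpos[1:])
    return _system(symbols, coords, provenance="fixture:biphenyl")


def naphthalene() -> MolecularSystem:
    """Two fused ideal hexagons (C–C 1.40 Å) sharing one edge; C₁₀H₈."""
    r = 1.40
    cx = r * math.cos(math.pi / 6)
    carbons: list[list[float]] = []
    for side in (-1, 1):
        center = (side * cx, 0.0)
        for theta_deg in (30, 90, 150, 210, 270, 330):
            theta = math.radians(theta_deg)
            p = [center[0] + r * math.cos(theta), center[1] + r * math.sin(theta), 0.0]
            if not any(np.allclose(p, q, atol=1e-6) for q in carbons):
                carbons.append(p)
    symbols = ["C"] * len(carbons)
    coords = list(carbons)
    for p in carbons:
        if abs(p[0]) < 1e-6:
            continue  # fusion carbons carry no H
        center = (math.copysign(cx, p[0]), 0.0)
        v = np.array([p[0] - center[0], p[1] - center[1], 0.0])
        v /= np.linalg.norm(v)
        coords.append(list(np.array(p) + _CH * v))
        symbols.append("H")
    return _system(symbols, coords, provenance="fixture:naphthalene")


def cubane_skeleton(edge: float = 1.55, with_h: bool = True) -> MolecularSystem:
    """C₈ cube (optionally H-capped along the body diagonals)."""
    h = edge / 2
    corners = [[sx * h, sy * h, sz * h]
               for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)]
    symbols = ["C"] * 8
    coords = list(corners)
    if with_h:
        for p in corners:
            v = np.array(p) / np.linalg.norm(p)
            coords.append(list(np.array(p) + _CH * v))
            symbols.append("H")
    return _system(symbols, coords, provenance="fixture:cubane")


def nacl_pair(r: float = 2.4) -> MolecularSystem:
    return _system(["Na", "Cl"], [[0, 0, 0], [r, 0, 0]], provenance="fixture:nacl")


def dinitrogen(r: float = 1.10) -> MolecularSystem:
    return _system(["N", "N"], [[0, 0, 0], [r, 0, 0]], provenance="fixture:n2")


# Frozen MMFF94-relaxed celecoxib conformer (synthetic geometry generated
# from the molecule's connectivity; heavy atoms first, hydrogens appended).
_CELECOXIB_XYZ = """\
C -4.2322 -2.6216 -2.2452
C -3.4467 -1.5135 -1.6078
C -3.0230 -1.6198 -0.2783
C -2.2655 -0.6024 0.3074
C -1.9015 0.5265 -0.4363
C -1.1201 1.5976 0.1744
C -1.5460 2.8894 0.4234
C -0.5250 3.5068 1.1753
C -0.5343 4.9086 1.7235
F -1.6604 5.5842 1.3601
F 0.5151 5.6479 1.2760
F -0.4928 4.9364 3.0817
N 0.4918 2.6540 1.3793
N 0.1692 1.5140 0.7022
C 1.1515 0.4746 0.6154
C 2.2610 0.5183 1.4824
C 3.2454 -0.4723 1.4361
C 3.1364 -1.5038 0.5037
S 4.3866 -2.7594 0.4501
N 5.5955 -1.9945 -0.4383
O 3.9175 -3.8400 -0.3866
O 4.8783 -2.9694 1.7902
C 2.0499 -1.5597 -0.3702
C 1.0641 -0.5668 -0.3188
C -2.3274 0.6353 -1.7649
C -3.0853 -0.3829 -2.3493
H -4.8580 -3.1323 -1.5057
H -4.8996 -2.2314 -3.0208
H -3.5520 -3.3499 -2.6972
H -3.2848 -2.4947 0.3135
H -1.9625 -0.7017 1.3477
H -2.5024 3.3148 0.1460
H 2.3638 1.3138 2.2203
H 4.0829 -0.4341 2.1307
H 5.7273 -2.4971 -1.3177
H 5.4216 -1.0014 -0.5880
H 1.9593 -2.3652 -1.0969
H 0.2634 -0.6304 -1.0477
H -2.0654 1.5078 -2.3592
H -3.3956 -0.2856 -3.3876
"""


def celecoxib() -> MolecularSystem:
    """Celecoxib (C₁₇H₁₄F₃N₃O₂S): a pyrazole core carrying a tolyl ring
    and a benzenesulfonamide ring through two biaryl bridge bonds."""
    symbols, coords = [], []
    for line in _CELECOXIB_XYZ.strip().splitlines():
        parts = line.split()
        symbols.append(parts[0])
        coords.append([float(v) for v in parts[1:4]])
    return _system(symbols, coords, provenance="fixture:celecoxib")
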