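"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the library's own computational paths:
d-spacings come from an explicit reciprocal-basis construction, orbit
reduction from a naive exhaustive partition, and map values from direct
Fourier summation.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from natsad.symmetry import TDEN, SpaceGroup, UnitCell

# every bundled space group with a compatible cell family and a d_min that
# keeps the enumeration below ~5000 reflections
BUNDLED_GROUPS = {
    "P1": ("triclinic", 3.0),
    "P21": ("monoclinic", 3.0),
    "C2": ("monoclinic", 3.0),
    "P212121": ("orthorhombic", 3.0),
    "C2221": ("orthorhombic", 3.0),
    "I222": ("orthorhombic", 3.0),
    "F222": ("orthorhombic", 3.0),
    "P41212": ("tetragonal", 3.0),
    "P43212": ("tetragonal", 3.0),
    "P42212": ("tetragonal", 3.0),
    "I4": ("tetragonal", 3.0),
    "I41": ("tetragonal", 3.0),
    "P3121": ("hexagonal", 3.0),
    "P3221": ("hexagonal", 3.0),
    "R3": ("hexagonal", 3.0),
    "P61": ("hexagonal", 3.0),
    "P65": ("hexagonal", 3.0),
    "P6122": ("hexagonal", 3.0),
}


def random_cell(system: str, rng: np.random.Generator) -> UnitCell:
    """A random small cell consistent with the given crystal system."""
    ln = lambda: float(rng.uniform(12.0, 22.0))
    if system == "triclinic":
        return UnitCell(ln(), ln(), ln(),
                        float(rng.uniform(80, 100)),
                        float(rng.uniform(80, 100)),
                        float(rng.uniform(80, 100)))
    if system == "monoclinic":
        return UnitCell(ln(), ln(), ln(), 90.0, float(rng.uniform(92, 110)), 90.0)
    if system == "orthorhombic":
        return UnitCell(ln(), ln(), ln())
    if system == "tetragonal":
        a = ln()
        return UnitCell(a, a, ln())
    if system == "hexagonal":
        a = ln()
        return UnitCell(a, a, ln(), 90.0, 90.0, 120.0)
    raise ValueError(system)


def reciprocal_basis(cell: UnitCell) -> np.ndarray:
    """Reciprocal basis vectors (rows), built from explicit cross products."""
    a, b, c = cell.a, cell.b, cell.c
    al, be, ga = (math.radians(x) for x in (cell.alpha, cell.beta, cell.gamma))
    # direct basis in Cartesian coordinates
    va = np.array([a, 0.0, 0.0])
    vb = np.array([b * math.cos(ga), b * math.sin(ga), 0.0])
    cx = c * math.cos(be)
    cy = c * (math.cos(al) - math.cos(be) * math.cos(ga)) / math.sin(ga)
    cz = math.sqrt(max(c * c - cx * cx - cy * cy, 0.0))
    vc = np.array([cx, cy, cz])
    vol = float(np.dot(va, np.cross(vb, vc)))
    return np.array([np.cross(vb, vc), np.cross(vc, va), np.cross(va, vb)]) / vol


def oracle_d(cell: UnitCell, hkl) -> float:
    """d-spacing from the reciprocal basis, independent of the metric tensor."""
    rb = reciprocal_basis(cell)
    s = np.asarray(hkl, dtype=float) @ rb
    return 1.0 / float(np.linalg.norm(s))


def oracle_enumerate(cell: UnitCell, d_min: float) -> list[tuple[int, int, int]]:
    """Brute-force full-sphere enumeration using the oracle d-spacing."""
    out = []
    hmax = [int(math.ceil(ax / d_min)) + 1 for ax in (cell.a, cell.b, cell.c)]
    for h in range(-hmax[0], hmax[0] + 1):
        for k in range(-hmax[1], hmax[1] + 1):
            for l in range(-hmax[2], hmax[2] + 1):
                if (h, k, l) == (0, 0, 0):
                    continue
                if oracle_d(cell, (h, k, l)) >= d_min - 1e-9:
                    out.append((h, k, l))
    return out


def oracle_is_absent(sg: SpaceGroup, hkl) -> bool:
    """Phase-restriction test applied operator by operator, by hand."""
    h = np.asarray(hkl, dtype=int)
    for op in sg.operators:
        if tuple(h @ np.array(op.rot)) == tuple(h):
            phase = int(h @ np.array(op.tran)) % TDEN
            if phase != 0:
                return True
    return False


def oracle_orbits(
    sg: SpaceGroup, indices: list[tuple[int, int, int]], merge_friedel: bool
) -> list[set[tuple[int, int, int]]]:
    """Naive orbit partition by exhaustive operator application."""
    rots = [np.array(op.rot) for op in sg.operators]
    remaining = set(indices)
    orbits = []
    while remaining:
        h = remaining.pop()
        orbit = set()
        for rot in rots:
            img = tuple((np.array(h) @ rot).tolist())
            orbit.add(img)
            if merge_friedel:
                orbit.add(tuple(-x for x in img))
        orbit &= set(indices)
        orbit.add(h)
        remaining -= orbit
        orbits.append(orbit)
    return orbits


def oracle_unique_count(
    cell: UnitCell, sg: SpaceGroup, d_min: float, merge_friedel: bool = True
) -> int:
    indices = oracle_enumerate(cell, d_min)
    orbits = oracle_orbits(sg, indices, merge_friedel)
    return sum(1 for orb in orbits if not oracle_is_absent(sg, next(iter(orb))))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(987654321)
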