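"""Tetragonal d-spacings and unique-reflection counting.

For a tetragonal cell, 1/d^2 = (h^2 + k^2)/a^2 + l^2/c^2.  The unique
reflection count for Laue group 4/mmm enumerates every integer hkl inside
the resolution sphere and merges symmetry mates (Friedel pairs included;
4/mmm is centrosymmetric, order 16) into one representative per orbit.
Each 4/mmm orbit has exactly one representative in the wedge
h >= k >= 0, l >= 0, so the count is an exact enumeration of that wedge,
minus the axial reflections extinguished by the screw axes of P4(2)2(1)2
(00l with l odd; h00 with h odd — 0k0 reduces to h00 in the wedge).

Naive sphere-volume / 16 undercounts by several percent because orbits
lying on mirror planes (h = k, k = 0, l = 0) are smaller than 16; exact
enumeration handles the boundary automatically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "UnitCell",
    "ReflectionDomain",
    "d_spacing",
    "count_unique_reflections",
    "expected_observed",
]


@dataclass
class UnitCell:
    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.alpha, self.beta, self.gamma) <= 0:
            raise ValueError("cell parameters must be positive")

    @classmethod
    def tetragonal(cls, a: float, c: float) -> "UnitCell":
        return cls(a, a, c)

    @property
    def is_tetragonal(self) -> bool:
        return (abs(self.a - self.b) < 1e-6 and
                max(abs(x - 90.0) for x in (self.alpha, self.beta, self.gamma)) < 1e-6)


@dataclass
class ReflectionDomain:
    dmin: float
    laue_group: str = "4/mmm"
    screw_absences: str = "P42212"   # axial absences: 00l l odd; h00/0k0 odd

    def __post_init__(self):
        if self.dmin <= 0:
            raise ValueError("dmin must be positive")
        if self.laue_group != "4/mmm":
            raise ValueError(f"unsupported Laue group {self.laue_group!r}")


def d_spacing(cell: UnitCell, hkl) -> float:
    """d-spacing in A of reflection hkl for a tetragonal cell."""
    h, k, l = hkl
    if h == 0 and k == 0 and l == 0:
        raise ValueError("(0,0,0) has no d-spacing")
    if not cell.is_tetragonal:
        raise ValueError("cell is not tetragonal")
    inv_d2 = (h * h + k * k) / cell.a**2 + l * l / cell.c**2
    return 1.0 / np.sqrt(inv_d2)


def _axial_absent(h: int, k: int, l: int) -> bool:
    # P4(2)2(1)2: 4(2) along c extinguishes 00l with l odd;
    # 2(1) along a/b extinguishes h00 (and 0k0) with odd index
    if h == 0 and k == 0:
        return l % 2 == 1
    if k == 0 and l == 0:
        return h % 2 == 1
    if h == 0 and l == 0:
        return k % 2 == 1
    return False


def count_unique_reflections(cell: UnitCell, dom: ReflectionDomain,
                             apply_absences: bool = True) -> int:
    """Exact unique-reflection count to dmin for Laue group 4/mmm.

    Enumerates the asymmetric wedge h >= k >= 0, l >= 0 (one representative
    per orbit), keeping 0 < 1/d^2 <= 1/dmin^2, and removes screw-axis
    absences.  Vectorized over l for speed.
    """
    if not cell.is_tetragonal:
        raise ValueError("cell is not tetragonal")
    a, c, dmin = cell.a, cell.c, dom.dmin
    s2max = 1.0 / dmin**2
    hmax = int(np.floor(a / dmin))
    count = 0
    for h in range(hmax + 1):
        for k in range(h + 1):
            rem = s2max - (h * h + k * k) / a**2
            if rem < 0:
                break
            lmax = int(np.floor(c * np.sqrt(rem)))
            n = lmax + 1
            if h == 0 and k == 0:
                n -= 1  # exclude the origin
                if apply_absences:
                    n -= (lmax + 1) // 2  # 00l, l odd
            elif k == 0 and apply_absences:
                # h00 is the single l = 0 member of this (h, 0) column
                if h % 2 == 1:
                    n -= 1
            count += n
    return count


def expected_observed(theoretical: int, completeness: float) -> float:
    """Expected measured unique count at a given completeness fraction."""
    if not 0.0 <= completeness <= 1.0:
        raise ValueError("completeness must be in [0, 1]")
    return theoretical * completeness
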