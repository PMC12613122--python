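"""Contracted Cartesian Gaussian orbitals evaluated on quadrature grids."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .grids import QuadratureGrid

__all__ = ["Primitive", "GaussianOrbital", "primitive_norm", "s_orbital", "p_orbital"]


@dataclass(frozen=True)
class Primitive:
    """One Cartesian Gaussian primitive c * x^lx y^ly z^lz exp(-a r^2)."""

    center: tuple[float, float, float]
    exponent: float
    angular: tuple[int, int, int]
    coefficient: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.exponent) or self.exponent <= 0:
            raise ValueError(f"exponent must be positive and finite, got {self.exponent}")
        if not np.isfinite(self.coefficient):
            raise ValueError("coefficient must be finite")
        if len(self.angular) != 3 or any(int(l) != l or l < 0 for l in self.angular):
            raise ValueError(f"angular momentum must be nonnegative ints, got {self.angular}")


def _double_factorial(n: int) -> int:
    out = 1
    while n > 1:
        out *= n
        n -= 2
    return out


def primitive_norm(exponent: float, angular: Sequence[int]) -> float:
    """Normalization constant of a Cartesian Gaussian primitive."""
    lx, ly, lz = (int(l) for l in angular)
    l = lx + ly + lz
    num = (2 * exponent / np.pi) ** 0.75 * (4 * exponent) ** (l / 2)
    den = np.sqrt(
        _double_factorial(2 * lx - 1)
        * _double_factorial(2 * ly - 1)
        * _double_factorial(2 * lz - 1)
    )
    return num / den


@dataclass(frozen=True)
class GaussianOrbital:
    """A molecular orbital as a fixed linear combination of primitives."""

    contractions: tuple[Primitive, ...]

    def __post_init__(self) -> None:
        prims = tuple(
            p if isinstance(p, Primitive) else Primitive(*p) for p in self.contractions
        )
        if not prims:
            raise ValueError("orbital needs at least one contraction")
        object.__setattr__(self, "contractions", prims)

    def evaluate(self, grid: QuadratureGrid) -> np.ndarray:
        """phi(r_k) at every grid point."""
        pts = grid.points
        out = np.zeros(pts.shape[0])
        for p in self.contractions:
            d = pts - np.asarray(p.center, float)
            r2 = np.einsum("ij,ij->i", d, d)
            poly = d[:, 0] ** p.angular[0] * d[:, 1] ** p.angular[1] * d[:, 2] ** p.angular[2]
            out += p.coefficient * poly * np.exp(-p.exponent * r2)
        return out

    def translated(self, shift) -> "GaussianOrbital":
        shift = np.asarray(shift, float)
        return GaussianOrbital(
            tuple(
                Primitive(tuple(np.asarray(p.center) + shift), p.exponent, p.angular, p.coefficient)
                for p in self.contractions
            )
        )


def s_orbital(center, exponent: float) -> GaussianOrbital:
    """Normalized single-primitive s orbital."""
    return GaussianOrbital(
        (Primitive(tuple(center), exponent, (0, 0, 0), primitive_norm(exponent, (0, 0, 0))),)
    )


def p_orbital(center, exponent: float, axis: int) -> GaussianOrbital:
    """Normalized single-primitive p orbital along x (0), y (1) or z (2)."""
    ang = tuple(1 if k == axis else 0 for k in range(3))
    return GaussianOrbital(
        (Primitive(tuple(center), exponent, ang, primitive_norm(exponent, ang)),)
    )


def evaluate_orbital(orbital: GaussianOrbital, grid: QuadratureGrid) -> np.ndarray:
    """Functional wrapper around :meth:`GaussianOrbital.evaluate`."""
    return orbital.evaluate(grid)
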