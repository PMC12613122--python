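"""Hole and electron distributions from excited-state configuration weights.

A TD-DFT excited state is a linear combination of singly excited (weight w,
occupied i -> virtual a) and de-excited (weight w', i <- a) configurations.
The hole density collects where amplitude leaves the occupied space and the
electron density where it arrives in the virtual space.  Each density splits
into a local term (a configuration with itself) and a cross term (coupling of
two configurations sharing the virtual orbital, for the hole, or sharing the
occupied orbital, for the electron); de-excitations enter both terms with a
negative sign.  Both densities integrate to sum(w^2) - sum(w'^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .grids import QuadratureGrid, becke_atomic_weights
from .orbitals import GaussianOrbital

__all__ = [
    "ConfigurationSet",
    "HoleElectronFields",
    "build_hole_electron",
    "integrate",
    "fragment_populations",
]


@dataclass(frozen=True)
class ConfigurationSet:
    """Excitation/de-excitation coefficients of one excited state.

    Each entry is ``(i, a, w)`` with occupied index i, virtual index a and
    real coefficient.  The de-excitation list is empty for TDA-like input.
    """

    excitations: tuple[tuple[int, int, float], ...]
    deexcitations: tuple[tuple[int, int, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        exc = tuple((int(i), int(a), float(w)) for i, a, w in self.excitations)
        dex = tuple((int(i), int(a), float(w)) for i, a, w in self.deexcitations)
        for name, entries in (("excitations", exc), ("deexcitations", dex)):
            pairs = [(i, a) for i, a, _ in entries]
            if len(pairs) != len(set(pairs)):
                raise ValueError(f"duplicate (i, a) pair in {name}")
            if any(not np.isfinite(w) for _, _, w in entries):
                raise ValueError(f"non-finite coefficient in {name}")
        if self.norm_target(exc, dex) <= 0:
            raise ValueError("sum(w^2) - sum(w'^2) must be positive")
        object.__setattr__(self, "excitations", exc)
        object.__setattr__(self, "deexcitations", dex)

    @staticmethod
    def norm_target(exc, dex) -> float:
        return sum(w * w for _, _, w in exc) - sum(w * w for _, _, w in dex)

    @property
    def norm(self) -> float:
        """sum(w^2) - sum(w'^2): the value both densities integrate to."""
        return self.norm_target(self.excitations, self.deexcitations)

    def orbital_indices(self) -> set[int]:
        out: set[int] = set()
        for i, a, _ in (*self.excitations, *self.deexcitations):
            out.update((i, a))
        return out


@dataclass(frozen=True)
class HoleElectronFields:
    """Hole/electron densities on a grid, with local/cross decomposition."""

    grid: QuadratureGrid
    hole_local: np.ndarray
    hole_cross: np.ndarray
    ele_local: np.ndarray
    ele_cross: np.ndarray
    norm: float  # sum(w^2) - sum(w'^2) of the source configurations

    @property
    def rho_hole(self) -> np.ndarray:
        return self.hole_local + self.hole_cross

    @property
    def rho_ele(self) -> np.ndarray:
        return self.ele_local + self.ele_cross


def integrate(values: np.ndarray, grid: QuadratureGrid) -> float:
    """Quadrature integral sum_k value_k * weight_k."""
    values = np.asarray(values, dtype=float)
    if values.shape != (grid.size,):
        raise ValueError(
            f"field length {values.shape} does not match grid size {grid.size}"
        )
    return float(values @ grid.weights)


def _density_terms(
    entries: Sequence[tuple[int, int, float]],
    phi: Mapping[int, np.ndarray],
    kind: str,
    include_cross: bool,
    npts: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Local and cross sums for one configuration list.

    For the hole the local term uses phi_i^2 and the cross term couples
    ordered pairs of entries sharing the virtual a; for the electron the
    local term uses phi_a^2 and the cross term couples pairs sharing the
    occupied i.
    """
    hole = kind == "hole"
    local = np.zeros(npts)
    cross = np.zeros(npts)
    for i, a, w in entries:
        local += w * w * phi[i if hole else a] ** 2
    if include_cross:
        for k, (i1, a1, w1) in enumerate(entries):
            for l, (i2, a2, w2) in enumerate(entries):
                if k == l:
                    continue
                same = (a1 == a2) if hole else (i1 == i2)
                if not same:
                    continue
                o1, o2 = (i1, i2) if hole else (a1, a2)
                cross += w1 * w2 * phi[o1] * phi[o2]
    return local, cross


def build_hole_electron(
    configs: ConfigurationSet,
    orbitals: Mapping[int, GaussianOrbital],
    grid: QuadratureGrid,
    include_cross: bool = True,
) -> HoleElectronFields:
    """Hole and electron densities of one excited state on ``grid``.

    ``orbitals`` maps every orbital index referenced by ``configs`` to its
    :class:`GaussianOrbital`.  ``include_cross=False`` zeroes the cross terms
    only (the local terms are unchanged).
    """
    missing = sorted(idx for idx in configs.orbital_indices() if idx not in orbitals)
    if missing:
        raise KeyError(f"configuration references unresolved orbital indices {missing}")
    needed = configs.orbital_indices()
    phi = {idx: orbitals[idx].evaluate(grid) for idx in needed}
    npts = grid.size

    hole_local = np.zeros(npts)
    hole_cross = np.zeros(npts)
    ele_local = np.zeros(npts)
    ele_cross = np.zeros(npts)
    for sign, entries in ((1.0, configs.excitations), (-1.0, configs.deexcitations)):
        hl, hc = _density_terms(entries, phi, "hole", include_cross, npts)
        el, ec = _density_terms(entries, phi, "ele", include_cross, npts)
        hole_local += sign * hl
        hole_cross += sign * hc
        ele_local += sign * el
        ele_cross += sign * ec
    return HoleElectronFields(
        grid=grid,
        hole_local=hole_local,
        hole_cross=hole_cross,
        ele_local=ele_local,
        ele_cross=ele_cross,
        norm=configs.norm,
    )


def fragment_populations(
    fields: HoleElectronFields,
    partition: Mapping[int, str],
    atom_centers: np.ndarray,
    method: str = "becke",
) -> dict[str, tuple[float, float]]:
    """Per-fragment (hole share, electron share), each summing to 1.

    ``partition`` maps every atom index (row of ``atom_centers``) to a
    fragment label.  Grid points are attributed to atoms by Becke fuzzy-cell
    weights (default) or by nearest nucleus, then aggregated per fragment and
    normalized by the total hole/electron integrals.
    """
    atom_centers = np.asarray(atom_centers, dtype=float).reshape(-1, 3)
    natom = atom_centers.shape[0]
    missing = [k for k in range(natom) if k not in partition]
    if missing:
        raise ValueError(f"atoms {missing} are not assigned to any fragment")

    if method == "becke":
        atom_w = becke_atomic_weights(fields.grid.points, atom_centers)  # (N, A)
    elif method == "nearest":
        d = np.linalg.norm(
            fields.grid.points[:, None, :] - atom_centers[None, :, :], axis=2
        )
        atom_w = np.zeros((fields.grid.size, natom))
        atom_w[np.arange(fields.grid.size), np.argmin(d, axis=1)] = 1.0
    else:
        raise ValueError(f"unknown attribution method {method!r}")

    wq = fields.grid.weights
    hole_atom = (fields.rho_hole * wq) @ atom_w  # (A,)
    ele_atom = (fields.rho_ele * wq) @ atom_w
    hole_tot = hole_atom.sum()
    ele_tot = ele_atom.sum()
    if hole_tot == 0 or ele_tot == 0:
        raise ValueError("zero total hole/electron population on this grid")

    out: dict[str, list[float]] = {}
    for atom, frag in partition.items():
        h, e = out.setdefault(frag, [0.0, 0.0])
        out[frag][0] = h + hole_atom[atom] / hole_tot
        out[frag][1] = e + ele_atom[atom] / ele_tot
    return {frag: (h, e) for frag, (h, e) in out.items()}
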