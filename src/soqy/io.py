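"""Readers and writers: excitation bundles (JSON), Molden, XYZ, cube.

The excitation bundle is this package's serialization of one complex's
TD-DFT outputs: geometry, orbitals (inline Gaussian shells or a Molden
reference), per-state configuration coefficients and transition dipoles,
and the S1-T1 spin-orbit coupling.  Quantum-chemistry program output
formats are version-brittle, so the bundle is the stable interchange point;
anything that can be parsed into this schema can feed the descriptor
engine.

Coordinates are stored internally in bohr; bundle geometry and XYZ files
are in angstrom and converted on input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .fields import ConfigurationSet
from .orbitals import GaussianOrbital, Primitive, primitive_norm
from .units import BOHR_PER_ANGSTROM

__all__ = [
    "ExcitationState",
    "ExcitationBundle",
    "read_excitation_bundle",
    "write_excitation_bundle",
    "read_molden",
    "read_xyz",
    "write_cube",
]

BUNDLE_SCHEMA = "soqy-bundle/1"


@dataclass(frozen=True)
class ExcitationState:
    """One excited state: energy, configurations, transition dipoles."""

    label: str
    energy_ev: float
    configurations: ConfigurationSet
    dipole_length: np.ndarray | None = None
    dipole_velocity: np.ndarray | None = None
    dipole_magnetic: np.ndarray | None = None


@dataclass(frozen=True)
class ExcitationBundle:
    """Parsed TD-DFT results of one complex."""

    elements: tuple[str, ...]
    coordinates_bohr: np.ndarray  # (A, 3)
    orbitals: dict[int, GaussianOrbital]
    states: dict[str, ExcitationState]
    soc_cm1: float | None = None
    provenance: dict = field(default_factory=dict)


def _parse_state(block: dict, errors: list[str], idx: int) -> ExcitationState | None:
    label = block.get("label")
    if label not in ("S1", "T1"):
        errors.append(f"states[{idx}]: label must be 'S1' or 'T1', got {label!r}")
        return None
    energy = block.get("energy_ev")
    if not isinstance(energy, (int, float)) or energy <= 0:
        errors.append(f"states[{idx}] ({label}): energy_ev must be a positive number")
        return None
    for key in ("configurations", "deexcitations"):
        for k, triple in enumerate(block.get(key, [])):
            if not (isinstance(triple, (list, tuple)) and len(triple) == 3):
                errors.append(
                    f"states[{idx}] ({label}): {key}[{k}] must be an [i, a, w] triple"
                )
                return None
    try:
        configs = ConfigurationSet(
            tuple(tuple(t) for t in block.get("configurations", [])),
            tuple(tuple(t) for t in block.get("deexcitations", [])),
        )
    except ValueError as exc:
        errors.append(f"states[{idx}] ({label}): {exc}")
        return None

    def vec(key):
        v = block.get(key)
        return None if v is None else np.asarray(v, dtype=float)

    return ExcitationState(
        label=label,
        energy_ev=float(energy),
        configurations=configs,
        dipole_length=vec("transition_dipole_length"),
        dipole_velocity=vec("transition_dipole_velocity"),
        dipole_magnetic=vec("transition_dipole_magnetic"),
    )


def _orbitals_from_shells(shells: list[dict], errors: list[str]) -> dict[int, GaussianOrbital]:
    out: dict[int, GaussianOrbital] = {}
    for k, shell in enumerate(shells):
        try:
            prims = tuple(
                Primitive(
                    tuple(np.asarray(p["center"], float) * BOHR_PER_ANGSTROM),
                    float(p["exponent"]),
                    tuple(int(l) for l in p["angular"]),
                    float(p["coefficient"]),
                )
                for p in shell["primitives"]
            )
            out[int(shell["index"])] = GaussianOrbital(prims)
        except (KeyError, ValueError, TypeError) as exc:
            errors.append(f"orbitals.shells[{k}]: {exc}")
    return out


def read_excitation_bundle(path: str | Path) -> ExcitationBundle:
    """Parse and validate a bundle file; collects every schema violation."""
    path = Path(path)
    doc = json.loads(path.read_text())
    errors: list[str] = []

    schema = doc.get("schema")
    if schema != BUNDLE_SCHEMA:
        raise ValueError(
            f"bundle schema {schema!r} is not {BUNDLE_SCHEMA!r}; "
            "re-export the bundle with this package's writer or migrate it"
        )
    geom = doc.get("geometry", {})
    elements = tuple(geom.get("elements", ()))
    coords = np.asarray(geom.get("coordinates_angstrom", []), dtype=float)
    if not elements or coords.shape != (len(elements), 3):
        errors.append("geometry must provide elements and matching (A, 3) coordinates_angstrom")

    orbital_spec = doc.get("orbitals", {})
    orbitals: dict[int, GaussianOrbital] = {}
    if "shells" in orbital_spec:
        orbitals = _orbitals_from_shells(orbital_spec["shells"], errors)
    elif "molden" in orbital_spec:
        mpath = Path(orbital_spec["molden"])
        if not mpath.is_absolute():
            mpath = path.parent / mpath
        _, orbitals = read_molden(mpath)
    else:
        errors.append("orbitals must provide 'shells' (inline) or 'molden' (path)")

    states: dict[str, ExcitationState] = {}
    for idx, block in enumerate(doc.get("states", [])):
        st = _parse_state(block, errors, idx)
        if st is not None:
            if st.label in states:
                errors.append(f"duplicate state label {st.label!r}")
            states[st.label] = st
    if not states:
        errors.append("bundle contains no valid states")

    if errors:
        raise ValueError("invalid excitation bundle:\n  - " + "\n  - ".join(errors))

    soc = doc.get("soc_cm1")
    return ExcitationBundle(
        elements=elements,
        coordinates_bohr=coords * BOHR_PER_ANGSTROM,
        orbitals=orbitals,
        states=states,
        soc_cm1=None if soc is None else float(soc),
        provenance=doc.get("provenance", {}),
    )


def write_excitation_bundle(bundle_doc: dict, path: str | Path) -> None:
    """Write a bundle document (dict in file schema) with the schema tag."""
    doc = dict(bundle_doc)
    doc.setdefault("schema", BUNDLE_SCHEMA)
    Path(path).write_text(json.dumps(doc, indent=2))


# --------------------------------------------------------------------------
# Molden
# --------------------------------------------------------------------------

_SHELL_COMPONENTS = {
    "s": [(0, 0, 0)],
    "p": [(1, 0, 0), (0, 1, 0), (0, 0, 1)],
    "d": [(2, 0, 0), (0, 2, 0), (0, 0, 2), (1, 1, 0), (1, 0, 1), (0, 1, 1)],
}


def read_molden(path: str | Path) -> tuple[list[tuple[str, np.ndarray]], dict[int, GaussianOrbital]]:
    """Minimal Molden reader: [Atoms], [GTO], [MO]; Cartesian s/p/d shells.

    Primitives are assumed unnormalized in the file and renormalized on
    load (the common Molden dialect).  Returns the atom list (element,
    position in bohr) and molecular orbitals indexed from 0 in file order.
    """
    lines = Path(path).read_text().splitlines()
    atoms: list[tuple[str, np.ndarray]] = []
    unit = BOHR_PER_ANGSTROM
    i = 0
    section = None
    gto_shells: list[tuple[int, str, list[tuple[float, float]]]] = []  # (atom, type, [(exp, coeff)])
    mo_coeffs: list[list[float]] = []

    while i < len(lines):
        line = lines[i].strip()
        low = line.lower()
        if low.startswith("[atoms]"):
            section = "atoms"
            unit = 1.0 if "au" in low else BOHR_PER_ANGSTROM
            i += 1
            continue
        if low.startswith("[gto]"):
            section = "gto"
            i += 1
            continue
        if low.startswith("[mo]"):
            section = "mo"
            i += 1
            continue
        if line.startswith("["):
            section = None
            i += 1
            continue

        if section == "atoms" and line:
            parts = line.split()
            atoms.append((parts[0], np.array([float(x) for x in parts[3:6]]) * unit))
        elif section == "gto" and line:
            parts = line.split()
            if len(parts) >= 1 and parts[0].isdigit() and len(parts) <= 2:
                atom_idx = int(parts[0]) - 1
                i += 1
                while i < len(lines) and lines[i].strip():
                    head = lines[i].split()
                    ltype = head[0].lower()
                    if ltype not in _SHELL_COMPONENTS:
                        raise ValueError(
                            f"unsupported shell type {ltype!r} in {path} "
                            "(s, p and d Cartesian shells are supported)"
                        )
                    nprim = int(head[1])
                    prims = []
                    for _ in range(nprim):
                        i += 1
                        ex, co = lines[i].replace("D", "E").replace("d", "e").split()[:2]
                        prims.append((float(ex), float(co)))
                    gto_shells.append((atom_idx, ltype, prims))
                    i += 1
                continue
        elif section == "mo" and line:
            low2 = low
            if "=" in low2 and not low2.startswith("occup"):
                pass  # Sym= / Ene= / Spin= headers
            elif low2.startswith("occup"):
                mo_coeffs.append([])
            else:
                parts = line.split()
                if len(parts) == 2 and mo_coeffs:
                    mo_coeffs[-1].append(float(parts[1]))
        i += 1

    # expand shells into contracted basis functions in Molden order
    funcs: list[tuple[Primitive, ...]] = []
    for atom_idx, ltype, prims in gto_shells:
        center = tuple(atoms[atom_idx][1])
        for ang in _SHELL_COMPONENTS[ltype]:
            funcs.append(
                tuple(
                    Primitive(center, ex, ang, co * primitive_norm(ex, ang))
                    for ex, co in prims
                )
            )

    orbitals: dict[int, GaussianOrbital] = {}
    for mo_idx, coeffs in enumerate(mo_coeffs):
        if len(coeffs) != len(funcs):
            raise ValueError(
                f"MO {mo_idx} has {len(coeffs)} coefficients for {len(funcs)} basis functions"
            )
        prims = []
        for c, func in zip(coeffs, funcs):
            if c == 0.0:
                continue
            prims.extend(
                Primitive(p.center, p.exponent, p.angular, c * p.coefficient) for p in func
            )
        if prims:
            orbitals[mo_idx] = GaussianOrbital(tuple(prims))
    return atoms, orbitals


# --------------------------------------------------------------------------
# XYZ and cube
# --------------------------------------------------------------------------

def read_xyz(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Elements and coordinates (converted to bohr) from an XYZ file."""
    lines = Path(path).read_text().splitlines()
    natoms = int(lines[0].split()[0])
    elements, coords = [], []
    for line in lines[2 : 2 + natoms]:
        parts = line.split()
        elements.append(parts[0])
        coords.append([float(x) for x in parts[1:4]])
    return elements, np.asarray(coords) * BOHR_PER_ANGSTROM


_ELEMENT_NUMBERS = {
    "H": 1, "B": 5, "C": 6, "N": 7, "O": 8, "F": 9, "P": 15, "S": 16,
    "Cl": 17, "Fe": 26, "Ru": 44, "Rh": 45, "Pd": 46, "Re": 75, "Os": 76,
    "Ir": 77, "Pt": 78, "Au": 79,
}


def write_cube(
    path: str | Path,
    values: np.ndarray,
    origin: np.ndarray,
    shape: tuple[int, int, int],
    spacing,
    elements: list[str] | None = None,
    coordinates_bohr: np.ndarray | None = None,
    comment: str = "soqy hole/electron density",
) -> None:
    """Write a scalar field on a rectilinear grid in Gaussian cube format."""
    values = np.asarray(values, float).reshape(shape)
    spacing = np.broadcast_to(np.asarray(spacing, float), (3,))
    elements = elements or []
    coords = np.asarray(coordinates_bohr if coordinates_bohr is not None else np.zeros((0, 3)))
    with open(path, "w") as fh:
        fh.write(f"{comment}\n")
        fh.write("generated by soqy\n")
        fh.write(f"{len(elements):5d} {origin[0]:12.6f} {origin[1]:12.6f} {origin[2]:12.6f}\n")
        for k in range(3):
            axis = [0.0, 0.0, 0.0]
            axis[k] = spacing[k]
            fh.write(f"{shape[k]:5d} {axis[0]:12.6f} {axis[1]:12.6f} {axis[2]:12.6f}\n")
        for el, xyz in zip(elements, coords):
            z = _ELEMENT_NUMBERS.get(el, 0)
            fh.write(f"{z:5d} {float(z):12.6f} {xyz[0]:12.6f} {xyz[1]:12.6f} {xyz[2]:12.6f}\n")
        flat = values.ravel()
        for start in range(0, flat.size, 6):
            fh.write(" ".join(f"{v:13.5e}" for v in flat[start : start + 6]) + "\n")
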