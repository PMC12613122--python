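"""High-level driver: excitation bundle -> 40-column descriptor record."""

from __future__ import annotations

import json
from importlib import resources
from typing import Mapping

from .excited import QCDRecord, StateDescriptors, compute_state_descriptors, spectroscopic_descriptors, assemble_qcd_record
from .fields import build_hole_electron
from .grids import becke_grid
from .io import ExcitationBundle

__all__ = ["default_partition", "qcd_from_bundle"]


def _metal_elements() -> set[str]:
    with resources.files("soqy.data").joinpath("metal_configurations.json").open() as fh:
        return set(json.load(fh)["elements"])


def default_partition(elements) -> dict[int, str]:
    """Atoms of d-block elements form the metal fragment; the rest, ligand."""
    metals = _metal_elements()
    return {i: ("metal" if el in metals else "ligand") for i, el in enumerate(elements)}


def qcd_from_bundle(
    bundle: ExcitationBundle,
    grid_level: int = 2,
    mode: str = "as-printed",
    hct_variant: str = "projection",
    partition: Mapping[int, str] | None = None,
) -> QCDRecord:
    """Compute the quantum-chemistry descriptor block of one complex.

    Requires both S1 and T1 states in the bundle.  The hole/electron
    densities are built on an atom-centered quadrature grid over the
    bundle's geometry; the metal/ligand partition defaults to grouping all
    d-block atoms into the metal fragment.
    """
    missing = [lbl for lbl in ("S1", "T1") if lbl not in bundle.states]
    if missing:
        raise ValueError(f"bundle lacks state(s) {missing}; S1 and T1 are required")
    if partition is None and len(bundle.elements):
        partition = default_partition(bundle.elements)
        if "metal" not in set(partition.values()):
            partition = None  # no metal atom: mlct undefined

    grid = becke_grid(bundle.coordinates_bohr, level=grid_level)
    per_state: dict[str, StateDescriptors] = {}
    for label in ("S1", "T1"):
        st = bundle.states[label]
        fields = build_hole_electron(st.configurations, bundle.orbitals, grid)
        per_state[label] = compute_state_descriptors(
            fields,
            energy_ev=st.energy_ev,
            dipole_length=st.dipole_length,
            dipole_velocity=st.dipole_velocity,
            dipole_magnetic=st.dipole_magnetic,
            partition=partition,
            atom_centers=bundle.coordinates_bohr if partition is not None else None,
            mode=mode,
            hct_variant=hct_variant,
        )
    s1 = bundle.states["S1"]
    spect = spectroscopic_descriptors(
        s1.energy_ev, s1.dipole_length, s1.dipole_velocity, s1.dipole_magnetic
    )
    return assemble_qcd_record(
        per_state["S1"],
        per_state["T1"],
        soc_cm1=bundle.soc_cm1,
        fosc1=spect["fosc1"],
        fosc2=spect["fosc2"],
    )
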