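"""Molecular-structure descriptors from an annotated connection table.

Transition-metal complexes with dative bonds do not survive round trips
through standard line notations, so structures enter as a small JSON
connection table with explicit hydrogens:

.. code-block:: json

    {
      "atoms": [{"element": "C", "formal_charge": 0, "metal_donor": false}],
      "bonds": [[0, 1, 1]],
      "charges": {"complex": 2, "ligands": 0, "metal": 2}
    }

``bonds`` entries are ``[i, j, order]`` with order 1/2/3 (dative bonds use
order 1); ``metal_donor`` flags the atoms coordinated to the metal center.
``charges`` carries the annotated net charge of the whole complex cation
(nc), of all ligands (lc) and of the metal center (mc); the donor-atom
charge cc is computed as the sum of formal charges over metal-donor atoms.

Functional-group counting follows a largest-group-wins containment
hierarchy: a carbonyl carbon claimed by an amide (CONH), ester/carboxyl
(COO) or aldehyde (CHO) match is not recounted as a plain carbonyl (CO);
pyrrole rings inside a matched BODIPY core are not recounted as pyrroles.
Generic ring counts (n-r5/n-r6) count every ring of that size.  Pyridine
rings fused into larger polycycles (e.g. phenanthroline) do count as
pyridines — named-ring counts look only at the ring's own atoms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import networkx as nx

__all__ = ["StructureDescriptorRecord", "structure_descriptors", "STRUCTURE_COLUMNS"]

STRUCTURE_COLUMNS = (
    "nc", "lc", "cc", "an", "mw",
    "n-X", "n-COO", "n-CO", "n-CHO", "n-CONH", "n-OH", "n-NH2", "n-S", "n-O",
    "n-CN", "n-bodipy", "n-py", "n-ph", "n-pyra", "n-pyrr", "n-r6", "n-r5",
    "n-db", "n-tb",
)

_HALOGENS = {"F", "Cl", "Br", "I"}


def _atomic_masses() -> dict[str, float]:
    with resources.files("soqy.data").joinpath("atomic_masses.json").open() as fh:
        return json.load(fh)["masses"]


@dataclass(frozen=True)
class StructureDescriptorRecord:
    """The 24 molecular-structure descriptors of one complex."""

    nc: int
    lc: int
    cc: int
    an: int
    mw: float
    counts: dict[str, int | None] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float | int | None]:
        out: dict[str, float | int | None] = {
            "nc": self.nc, "lc": self.lc, "cc": self.cc, "an": self.an, "mw": self.mw,
        }
        out.update({k: self.counts.get(k) for k in STRUCTURE_COLUMNS[5:]})
        return out


def _neighbors(bonds, idx):
    for i, j, order in bonds:
        if i == idx:
            yield j, order
        elif j == idx:
            yield i, order


def structure_descriptors(structure: dict) -> StructureDescriptorRecord:
    """Compute the Table-style structure descriptors from a connection table."""
    atoms = structure.get("atoms")
    if not atoms:
        raise ValueError("structure must provide a nonempty 'atoms' list")
    charges = structure.get("charges")
    if charges is None or not {"complex", "ligands", "metal"} <= set(charges):
        raise ValueError(
            "structure must provide 'charges' with keys complex/ligands/metal"
        )
    raw_bonds = structure.get("bonds", [])
    orders_known = all(len(b) >= 3 and b[2] is not None for b in raw_bonds)
    bonds = [(int(b[0]), int(b[1]), (int(b[2]) if len(b) >= 3 and b[2] is not None else None))
             for b in raw_bonds]

    elements = [a["element"] for a in atoms]
    masses = _atomic_masses()
    unknown = sorted({e for e in elements if e not in masses})
    if unknown:
        raise ValueError(f"no atomic mass on file for element(s) {unknown}")
    mw = sum(masses[e] for e in elements)
    an = len(atoms)
    donor_charge = sum(
        int(a.get("formal_charge", 0)) for a in atoms if a.get("metal_donor")
    )

    counts: dict[str, int | None] = {k: 0 for k in STRUCTURE_COLUMNS[5:]}
    counts["n-X"] = sum(e in _HALOGENS for e in elements)
    counts["n-S"] = elements.count("S")
    counts["n-O"] = elements.count("O")

    heavy_graph = nx.Graph()
    heavy_graph.add_nodes_from(
        i for i, e in enumerate(elements) if e != "H"
    )
    for i, j, order in bonds:
        if elements[i] != "H" and elements[j] != "H":
            heavy_graph.add_edge(i, j)

    rings = [frozenset(c) for c in nx.minimum_cycle_basis(heavy_graph)]
    counts["n-r5"] = sum(len(r) == 5 for r in rings)
    counts["n-r6"] = sum(len(r) == 6 for r in rings)

    if not orders_known:
        # without bond orders, unsaturation- and aromaticity-dependent counts
        # cannot be decided
        for key in ("n-db", "n-tb", "n-ph", "n-py", "n-pyra", "n-pyrr",
                    "n-bodipy", "n-COO", "n-CO", "n-CHO", "n-CONH", "n-OH",
                    "n-NH2", "n-CN"):
            counts[key] = None
        return StructureDescriptorRecord(
            nc=int(charges["complex"]), lc=int(charges["ligands"]),
            cc=donor_charge, an=an, mw=mw, counts=counts,
        )

    counts["n-db"] = sum(order == 2 for _, _, order in bonds)
    counts["n-tb"] = sum(order == 3 for _, _, order in bonds)

    def h_count(idx):
        return sum(elements[n] == "H" for n, _ in _neighbors(bonds, idx))

    # --- carbonyl family, largest group wins ------------------------------
    carbonyl_carbons: set[int] = set()
    for i, j, order in bonds:
        if order != 2:
            continue
        pair = {elements[i]: i, elements[j]: j}
        if set(pair) == {"C", "O"}:
            carbonyl_carbons.add(pair["C"])
    claimed: set[int] = set()
    for c in sorted(carbonyl_carbons):
        nbr = list(_neighbors(bonds, c))
        has_n = any(elements[n] == "N" and order == 1 for n, order in nbr)
        has_single_o = any(elements[n] == "O" and order == 1 for n, order in nbr)
        if has_n:
            counts["n-CONH"] += 1
        elif has_single_o:
            counts["n-COO"] += 1
        elif h_count(c) >= 1:
            counts["n-CHO"] += 1
        else:
            counts["n-CO"] += 1
        claimed.add(c)

    # hydroxyl: O-H whose oxygen is not part of a counted carbonyl group
    for idx, e in enumerate(elements):
        if e == "O" and h_count(idx) >= 1:
            heavy_nbrs = [n for n, _ in _neighbors(bonds, idx) if elements[n] != "H"]
            if not any(n in claimed for n in heavy_nbrs):
                counts["n-OH"] += 1
        if e == "N" and h_count(idx) == 2:
            heavy_nbrs = [n for n, _ in _neighbors(bonds, idx) if elements[n] != "H"]
            if not any(n in claimed for n in heavy_nbrs):
                counts["n-NH2"] += 1

    for i, j, order in bonds:
        if order == 3 and {elements[i], elements[j]} == {"C", "N"}:
            counts["n-CN"] += 1

    # --- named rings ------------------------------------------------------
    def ring_profile(ring):
        return sorted(elements[i] for i in ring)

    pyrrole_rings = []
    for ring in rings:
        prof = ring_profile(ring)
        if len(ring) == 6 and prof == ["C"] * 6:
            # phenyl: six sp2 carbons (each in at least one double bond)
            sp2 = all(
                any(order == 2 for _, order in _neighbors(bonds, i)) for i in ring
            )
            if sp2:
                counts["n-ph"] += 1
        elif len(ring) == 6 and prof == ["C"] * 5 + ["N"]:
            counts["n-py"] += 1
        elif len(ring) == 6 and prof == ["C"] * 4 + ["N", "N"]:
            counts["n-pyra"] += 1
        elif len(ring) == 5 and prof == ["C"] * 4 + ["N"]:
            pyrrole_rings.append(ring)

    # BODIPY core: boron bonded to two fluorines and two nitrogens that each
    # sit in a pyrrole-type five-ring; those pyrroles are consumed
    consumed: set[frozenset] = set()
    for idx, e in enumerate(elements):
        if e != "B":
            continue
        nbrs = list(_neighbors(bonds, idx))
        n_f = sum(elements[n] == "F" for n, _ in nbrs)
        n_atoms = [n for n, _ in nbrs if elements[n] == "N"]
        if n_f >= 2 and len(n_atoms) >= 2:
            member = [r for r in pyrrole_rings if any(n in r for n in n_atoms)]
            if len(member) >= 2:
                counts["n-bodipy"] += 1
                consumed.update(member[:2])
    counts["n-pyrr"] = sum(1 for r in pyrrole_rings if r not in consumed)

    return StructureDescriptorRecord(
        nc=int(charges["complex"]),
        lc=int(charges["ligands"]),
        cc=donor_charge,
        an=an,
        mw=mw,
        counts=counts,
    )
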