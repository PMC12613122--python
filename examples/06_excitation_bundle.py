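"""From a serialized TD-DFT bundle to the 40-column descriptor record.

Writes a minimal excitation bundle (geometry, inline Gaussian orbitals, S1
and T1 states, spin-orbit coupling), reads it back and computes the full
quantum-chemistry descriptor block.
"""

import json
import tempfile
from pathlib import Path

from soqy import qcd_from_bundle, read_excitation_bundle

bundle_doc = {
    "schema": "soqy-bundle/1",
    "geometry": {
        "elements": ["Ru", "N"],
        "coordinates_angstrom": [[0.0, 0.0, 0.0], [0.0, 0.0, 2.1]],
    },
    "orbitals": {
        "shells": [
            {"index": 0, "primitives": [
                {"center": [0.0, 0.0, 0.0], "exponent": 0.5,
                 "angular": [0, 0, 0], "coefficient": 0.423777}]},
            {"index": 1, "primitives": [
                {"center": [0.0, 0.0, 2.1], "exponent": 0.5,
                 "angular": [0, 0, 0], "coefficient": 0.423777}]},
        ]
    },
    "states": [
        {"label": "S1", "energy_ev": 2.4, "configurations": [[0, 1, 1.0]],
         "transition_dipole_length": [0.5, 0.0, 1.0],
         "transition_dipole_velocity": [0.4, 0.0, 0.9],
         "transition_dipole_magnetic": [0.0, 0.2, 0.0]},
        {"label": "T1", "energy_ev": 1.9, "configurations": [[0, 1, 1.0]]},
    ],
    "soc_cm1": 150.0,
    "provenance": {"program": "synthetic example (no DFT run)"},
}

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "complex.json"
    path.write_text(json.dumps(bundle_doc))
    bundle = read_excitation_bundle(path)
    record = qcd_from_bundle(bundle, grid_level=2)

row = record.as_row()
print(f"computed {len(row)} descriptors under mode={record.mode!r}")
for key in ("S-ee", "T-ee", "D-ee", "S-d", "S-mlct", "soc", "S1", "fosc1", "fosc2"):
    val = row[key]
    print(f"  {key:7s} {val:.4f}" if val is not None else f"  {key:7s} absent")
# D-ee is the singlet-triplet gap that controls intersystem crossing;
# S-mlct is the metal-to-ligand charge-transfer fraction of S1.
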