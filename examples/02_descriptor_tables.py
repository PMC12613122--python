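"""Structure, metal-centered and condition descriptors for one complex.

Annotates a minimal ruthenium complex as a JSON connection table, looks up
the free-atom metal configuration and the solvent dielectric constants, and
shows the dataset preprocessing rules on a small table.
"""

import pandas as pd

from soqy import (
    condition_descriptors,
    metal_descriptors,
    preprocess_dataset,
    structure_descriptors,
)

# a 2+ complex: Ru coordinated by five neutral N donors and one anionic O
structure = {
    "atoms": [
        {"element": "Ru", "formal_charge": 2, "metal_donor": False},
        {"element": "O", "formal_charge": -1, "metal_donor": True},
        *[{"element": "N", "formal_charge": 0, "metal_donor": True} for _ in range(5)],
    ],
    "bonds": [[0, k, 1] for k in range(1, 7)],
    "charges": {"complex": 2, "ligands": 0, "metal": 2},
}
rec = structure_descriptors(structure)
print(f"complex charge nc={rec.nc}, ligand charge lc={rec.lc}, donor charge cc={rec.cc}")
print(f"atoms an={rec.an}, molar mass mw={rec.mw:.2f} g/mol")

metal = metal_descriptors("Ru", metal_charge=2, metal_count=1)
print(f"\nRu free atom: period cp={metal.cp}, outer electrons "
      f"s={metal.cs} d={metal.cd} f={metal.cf}  (configuration [Kr]4d7 5s1)")

cond = condition_descriptors("water", wavelength_nm=450)
print(f"\nwater: eps={cond.eps}, epsinf={cond.epsinf}, irradiation wl={cond.wl} nm")

# preprocessing: drop near-dark yields and wavelength-inconsistent groups
frame = pd.DataFrame({
    "identifier": ["a", "b", "c", "c"],
    "phi_delta": [0.005, 0.42, 0.90, 0.30],
    "wl": [450.0, 450.0, 450.0, 600.0],
})
kept, log = preprocess_dataset(frame)
print(f"\npreprocessing kept {len(kept)}/{len(frame)} rows; exclusions:")
print(log.to_string(index=False))
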