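"""Physical constants and unit conversions (CODATA 2018)."""

BOHR_PER_ANGSTROM = 1.8897259886
ANGSTROM_PER_BOHR = 1.0 / BOHR_PER_ANGSTROM

#: hc in eV*nm, for wavelength <-> energy conversion
EV_NM = 1239.841984

HARTREE_PER_EV = 1.0 / 27.211386245988
EV_PER_HARTREE = 27.211386245988


def ev_to_nm(energy_ev: float) -> float:
    """Photon wavelength in nm for an excitation energy in eV."""
    if energy_ev <= 0:
        raise ValueError(f"excitation energy must be positive, got {energy_ev}")
    return EV_NM / energy_ev
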