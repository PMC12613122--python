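{
  "_comment": "Ground-state outer electron configurations of the free neutral d-block atoms (NIST Atomic Spectra Database, periods 4-6). cs/cd/cf are the outermost s/d/f electron counts; period is the row of the periodic table.",
  "version": 1,
  "elements": {
    "Sc": {"period": 4, "cs": 2, "cd": 1, "cf": 0},
    "Ti": {"period": 4, "cs": 2, "cd": 2, "cf": 0},
    "V":  {"period": 4, "cs": 2, "cd": 3, "cf": 0},
    "Cr": {"period": 4, "cs": 1, "cd": 5, "cf": 0},
    "Mn": {"period": 4, "cs": 2, "cd": 5, "cf": 0},
    "Fe": {"period": 4, "cs": 2, "cd": 6, "cf": 0},
    "Co": {"period": 4, "cs": 2, "cd": 7, "cf": 0},
    "Ni": {"period": 4, "cs": 2, "cd": 8, "cf": 0},
    "Cu": {"period": 4, "cs": 1, "cd": 10, "cf": 0},
    "Zn": {"period": 4, "cs": 2, "cd": 10, "cf": 0},
    "Y":  {"period": 5, "cs": 2, "cd": 1, "cf": 0},
    "Zr": {"period": 5, "cs": 2, "cd": 2, "cf": 0},
    "Nb": {"period": 5, "cs": 1, "cd": 4, "cf": 0},
    "Mo": {"period": 5, "cs": 1, "cd": 5, "cf": 0},
    "Tc": {"period": 5, "cs": 2, "cd": 5, "cf": 0},
    "Ru": {"period": 5, "cs": 1, "cd": 7, "cf": 0},
    "Rh": {"period": 5, "cs": 1, "cd": 8, "cf": 0},
    "Pd": {"period": 5, "cs": 0, "cd": 10, "cf": 0},
    "Ag": {"period": 5, "cs": 1, "cd": 10, "cf": 0},
    "Cd": {"period": 5, "cs": 2, "cd": 10, "cf": 0},
    "La": {"period": 6, "cs": 2, "cd": 1, "cf": 0},
    "Hf": {"period": 6, "cs": 2, "cd": 2, "cf": 14},
    "Ta": {"period": 6, "cs": 2, "cd": 3, "cf": 14},
    "W":  {"period": 6, "cs": 2, "cd": 4, "cf": 14},
    "Re": {"period": 6, "cs": 2, "cd": 5, "cf": 14},
    "Os": {"period": 6, "cs": 2, "cd": 6, "cf": 14},
    "Ir": {"period": 6, "cs": 2, "cd": 7, "cf": 14},
    "Pt": {"period": 6, "cs": 1, "cd": 9, "cf": 14},
    "Au": {"period": 6, "cs": 1, "cd": 10, "cf": 14},
    "Hg": {"period": 6, "cs": 2, "cd": 10, "cf": 14}
  }
}
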