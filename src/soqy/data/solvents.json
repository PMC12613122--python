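{
  "_comment": "Static dielectric constants (eps, 25 C) and optical dielectric constants (epsinf = n_D^2) of common photochemistry solvents. Values follow the Minnesota solvent descriptor database / CRC Handbook.",
  "version": 1,
  "solvents": {
    "water":            {"eps": 78.355, "epsinf": 1.7764},
    "acetonitrile":     {"eps": 35.688, "epsinf": 1.8069},
    "dmso":             {"eps": 46.826, "epsinf": 2.1883},
    "methanol":         {"eps": 32.613, "epsinf": 1.7657},
    "ethanol":          {"eps": 24.852, "epsinf": 1.8526},
    "dichloromethane":  {"eps": 8.930,  "epsinf": 2.0283},
    "chloroform":       {"eps": 4.7113, "epsinf": 2.0906},
    "acetone":          {"eps": 20.493, "epsinf": 1.8463},
    "dmf":              {"eps": 37.219, "epsinf": 2.0463},
    "toluene":          {"eps": 2.3741, "epsinf": 2.2383},
    "benzene":          {"eps": 2.2706, "epsinf": 2.2533},
    "thf":              {"eps": 7.4257, "epsinf": 1.9740},
    "1-propanol":       {"eps": 20.524, "epsinf": 1.9195},
    "2-propanol":       {"eps": 19.264, "epsinf": 1.8989},
    "hexane":           {"eps": 1.8819, "epsinf": 1.8865},
    "cyclohexane":      {"eps": 2.0165, "epsinf": 2.0333},
    "ethyl acetate":    {"eps": 5.9867, "epsinf": 1.8829}
  },
  "aliases": {
    "h2o": "water",
    "pbs": "water",
    "phosphate buffer": "water",
    "d2o": "water",
    "meoh": "methanol",
    "etoh": "ethanol",
    "mecn": "acetonitrile",
    "ch3cn": "acetonitrile",
    "acn": "acetonitrile",
    "dcm": "dichloromethane",
    "ch2cl2": "dichloromethane",
    "chcl3": "chloroform",
    "dimethyl sulfoxide": "dmso",
    "dimethylformamide": "dmf",
    "tetrahydrofuran": "thf"
  }
}
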