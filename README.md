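# soqy

Excited-state hole–electron descriptors and small-data QSPR models for the
singlet-oxygen quantum yield (Φ_Δ) of transition-metal-complex
photosensitizers.

## The problem

Photodynamic therapy uses light-activated photosensitizers — often
hexacoordinate Ru/Ir/Re complexes — to generate cytotoxic singlet oxygen.
The key figure of merit, Φ_Δ ∈ (0, 1], is laborious to measure, and the
experimental record is small (on the order of a hundred complexes), which
rules out deep models and puts a premium on physically meaningful
descriptors. `soqy` implements a DFT→ML workflow for this regime:

1. **Descriptor engine.** From a TD-DFT excited state written as a sum of
   singly (de-)excited configurations with coefficients w (w′), the hole
   and electron densities are

   ρ^hole = Σ_{i→a} w² φ_i² + Σ_{i→a} Σ_{j≠i→a} w_i^a w_j^a φ_i φ_j − (de-excitation terms)

   and analogously ρ^ele over the virtual orbitals. From these the engine
   computes the standard charge-transfer indices — Sr (hole–electron
   overlap), D (centroid separation), Δσ (spread difference), H_CT (mean
   spread along the CT direction), H, t = D − H_CT, and the hole/electron
   delocalization indices HDI/EDI — plus excitation energies, oscillator
   strengths f = (2/3)E|μ|² (length gauge) and (2/3)|μ_v|²/E (velocity
   gauge), transition-dipole magnitudes, the S1–T1 spin–orbit coupling
   (parsed, not computed), and a metal-to-ligand charge-transfer fraction.
   S1 values, T1 values and their differences form a fixed 40-column block.

2. **Descriptor tables.** Structure descriptors (charges, size, functional
   group counts with a largest-group-wins containment rule) from an
   annotated JSON connection table; metal-centered descriptors (period and
   free-atom s/d/f electron counts, e.g. Ru [Kr]4d⁷5s¹ → cp=5, cs=1, cd=7,
   cf=0); solvent dielectric constants and irradiation wavelength.

3. **Modeling protocol.** Min–max normalization fitted on training data
   only (spin–orbit coupling log-transformed first), 90:10 random split,
   six single regressors (SVR, KRR, GPR, XGBoost, RFR, KNR) with seeded
   random hyperparameter search, leave-one-out Q² as the stability
   measure, Shapley-based descriptor ranking, a filter loop over the top
   30–50 descriptors in steps of 5, a QSPR gate (Q² ≥ 0.6 and external
   R² ≥ 0.6), and two hybrids: a delta-learning stack (SVR base + KRR
   residual layer) and a mixture-of-experts with convex weights.

No quantum-chemistry program is run: the engine consumes serialized
"excitation bundles" (JSON; orbitals inline or via Molden), and a
synthetic-data module generates analytic toy excitations and feature tables
with planted signal for testing every stage end to end.

## Worked example

```sh
python examples/01_hole_electron_descriptors.py
```

prints, for a toy excitation whose hole sits on a Gaussian orbital
(α = 0.5) at the origin and whose electron sits 4 bohr away:

```
D index (bohr)       : 4.0000   (closed form 4.0000)
sigma per axis (bohr): 0.7071   (closed form 0.7071)
H_CT (bohr)          : 0.7071   (closed form 0.7071)
t index (bohr)       : 3.2929   (closed form 3.2929)
HDI                  : 6.3494   (closed form 6.3494)
```

D is the hole→electron centroid distance; σ = 1/(2√α) is the per-axis
spread of the Gaussian density; t > 0 marks a genuine charge-transfer
state. The other examples cover descriptor tables
(`02_descriptor_tables.py`), single-model training with the QSPR gate
(`03_train_single_models.py`), Shapley ranking + the descriptor filter
(`04_descriptor_filter.py`), the hybrids (`05_hybrid_models.py`) and the
bundle-to-descriptor pipeline (`06_excitation_bundle.py`). A thin CLI
(`soqy simulate|qcd|featurize|train|filter-descriptors|predict|explain`)
wraps the same functions for shell use.

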