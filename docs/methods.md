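# Methods

## Hole–electron analysis

An excited state from a linear-response TD-DFT calculation is a sum of
singly excited configurations i→a with coefficients w_i^a and, for full TD
(non-TDA) references, de-excited configurations with coefficients w′_i^a.
The hole density collects the occupied-space amplitude loss and the
electron density the virtual-space gain; each splits into a local term
(configurations with themselves) and a cross term (pairs of configurations
sharing the virtual orbital for the hole, or the occupied orbital for the
electron). De-excitations enter both with a negative sign. Cross-term sums
iterate ordered pairs, exactly as the defining double sums are written, and
the implementation is regression-tested against a literal pairwise loop.

Both densities integrate to Σw² − Σw′² when the orbitals are orthonormal;
pointwise negativity is allowed (full-TD densities are signed), and only
the integrals are constrained. Centroids and spreads are computed on the
signed density normalized by its integral; the fraction of quadrature
weight with negative density is recorded so heavily negative cases can be
flagged (threshold 5%).

### Scalar indices

With Γ_s the centroid and σ_λ^s = sqrt(∫(λ−Γ_s)²ρ̂_s dr) the per-axis RMS
spread of state s ∈ {hole, ele}:

* **D** — Euclidean distance between hole and electron centroids.
* **Δσ** — |σ^ele| − |σ^hole| (norms of the per-axis spread vectors).
* **H** — (|σ^ele| + |σ^hole|)/2, the overall average width.
* **H_CT** — average spread along the CT direction u (unit vector from
  hole to electron centroid). The default computes the directional
  spreads sqrt(u·Σ_s·u) from the full second-moment matrices Σ_s and
  averages them. This is the faithful reading of "spread in the CT
  direction": it coincides with the per-axis formula (σ-vector dotted or
  crossed with u) whenever u is a coordinate axis, and unlike it is
  exactly invariant under rigid rotations — per-axis spreads are not the
  components of a vector, so the dot/cross forms are frame-dependent
  (visible even for spherical densities). Both per-axis variants remain
  available (`hct_variant="dot"`/`"cross"`) for auditing against codes
  that use them.
* **t** = D − H_CT, the net hole–electron separation; t > 0 indicates a
  charge-transfer state. The identity t = D − H_CT holds exactly by
  construction.
* **Sr, HDI, EDI** — overlap and delocalization integrals. Two
  conventions exist in the literature and the package implements both:
  `as-printed` (Sr = ∫ρ_hole ρ_ele dr, HDI = 100∫ρ_hole² dr) and `compat`
  (Sr = ∫√(ρ_hole ρ_ele) dr over the nonnegative part,
  HDI = 100·√(∫ρ²dr)), the latter matching the square-root forms common in
  hole–electron analysis tools. The mode is recorded in every record's
  provenance; compat-mode Sr lies in [0, 1] with equality for identical
  densities.
* **mlct** — no standard formula exists; the package defines it as
  (hole share on the metal fragment) × (electron share on all ligand
  fragments), an independent-fragment approximation, with fragment shares
  from Becke fuzzy-cell attribution (nearest-nucleus attribution is an
  option). The definition name is carried in provenance.

When the centroids coincide the CT direction is undefined; H_CT is then
defined as 0 and the record flags the degenerate path.

Spatial indices are computed in bohr and reported in Å (1 Å =
1.8897259886 bohr); energies in eV, S1 wavelength in nm
(λ = 1239.841984/E), spin–orbit coupling in cm⁻¹, dipoles in atomic
units. Oscillator strengths use the standard gauge formulas
f_len = (2/3)E|μ_len|² and f_vel = (2/3)|μ_vel|²/E with E in hartree.

## Quadrature

Integrals use an atom-centered molecular grid: Gauss–Chebyshev
(second-kind) radial points under Becke's rational map r = r_m(1+x)/(1−x)
(r_m = 1 bohr), a spherical product grid (Gauss–Legendre in cos θ ×
uniform in φ) for the angular part, and Becke fuzzy-cell weights (three
smoothing iterations, equal atomic radii) to partition overlapping atomic
grids. Product angular grids integrate spherical harmonics up to degree
2n_θ−1 exactly, which is ample for densities of s/p/d Gaussians; Lebedev
grids would reduce the point count but add nothing at these angular
orders. Three levels are exposed: level 1 (28×10×20 per atom), level 2
(default, 45×14×28; descriptor integrals of well-behaved Gaussian
densities converge to ~1e-4 relative), level 3 (70×20×40). A rectilinear
uniform grid is provided for cube-file export and brute-force reference
integrals. Default integral tolerance for validity checks is 1e-3
relative on the default grid.

## Descriptor tables

* **Structure block** (24 columns). Input is an annotated JSON connection
  table with explicit hydrogens — line notations round-trip poorly for
  dative bonds in metal complexes. Functional groups follow a
  largest-group-wins containment rule: a carbonyl carbon claimed by amide
  (C(=O)N), ester/carboxyl (C(=O)O), or aldehyde (C(=O)H) is not
  recounted as a plain carbonyl; carboxyl O–H is not a hydroxyl; amide N
  is not an amine; pyrroles inside a matched BODIPY core (B bonded to two
  F and two pyrrole nitrogens) are not recounted as pyrroles. Named rings
  are classified by their own atoms (6-ring of sp² carbons → phenyl; one
  ring nitrogen → pyridine; two → pyrazine; 5-ring with one N → pyrrole),
  so a pyridine fused into a phenanthroline still counts as a pyridine;
  generic r5/r6 counts (minimum cycle basis) count every ring. Missing
  bond orders leave the unsaturation-dependent counts absent rather than
  zero. The donor-atom charge cc is the sum of formal charges over atoms
  flagged as metal donors; nc/lc/mc are annotations.
* **Metal block** (6 columns). Pure table lookups from the bundled
  free-neutral-atom ground-state configurations (NIST), periods 4–6 of
  the d block; charge and count are pass-through annotations.
* **Condition block** (3 columns). Solvent static and optical dielectric
  constants from a bundled, versioned table (Minnesota solvent
  descriptors / CRC values) with name aliases and nearest-name
  suggestions on miss; irradiation wavelength in nm is passed through.
  (One published descriptor table mislabels the wavelength row with a
  metal-orbital description; the wavelength reading is the only one
  consistent with the data-collection protocol.)

Preprocessing removes records with Φ_Δ < 0.01 and drops same-complex
groups measured only at different wavelengths when their max/min Φ_Δ
ratio exceeds a threshold (default 2.0 — the qualitative rule "excessive
differences" is not quantified anywhere, so the threshold is exposed and
every exclusion is logged with its rule).

## Modeling protocol

Descriptors are min–max normalized with training-set statistics only
(test rows may leave [0, 1]; constant columns map to 0 and are flagged);
the spin–orbit coupling is log10-transformed first with a floor of 1e-3
cm⁻¹ so zero-coupling toy inputs stay finite. The split is random 90:10
(136 rows → 122/14), deterministic under a seed.

Six families are supported with these search spaces (log-uniform unless
stated): SVR C ∈ [1e-2, 1e3], ε ∈ [1e-4, 1e-1], kernel ∈ {RBF, linear,
poly}; KRR α ∈ [1e-6, 1e1], RBF γ ∈ [1e-4, 1e2]; GPR noise ∈ [1e-8,
1e-1], length scale ∈ [1e-2, 1e2], restarts 0–2; XGBoost depth 2–8,
learning rate [1e-3, 0.3], estimators 50–500, subsample/colsample
[0.5, 1]; RFR trees 50–500, depth 2–12, feature fraction [0.2, 1]; KNR
k 1–15, weights {uniform, distance}, p ∈ {1, 2}. Hyperparameters are
chosen by a seeded sequential random search (the budget counts sampled
configurations; default 30, study protocol 60) maximizing 5-fold CV R²
(LOO optional but costly inside the search); the best configuration is
refit on all training rows. The SVR solver is capped at 1e5 iterations —
libsvm can stall for poly kernels with large C on this kind of data.

LOO Q² = 1 − PRESS/SS_tot refits the normalizer and model inside every
fold; it is tested for exact agreement with a literal leave-one-out loop.
Metrics are R², MaxAE, MAE, MSE. The QSPR gate passes a model iff
cross-validated Q² ≥ 0.6 and external R² ≥ 0.6 (thresholds configurable).

**Attribution.** Descriptor importance uses Shapley values estimated by
permutation sampling under an interventional background (default 24
background rows, 8 antithetic orderings): features are switched in one at
a time along each sampled ordering and the marginal change in the mean
prediction is credited to the switched feature. Per ordering the
attributions sum exactly to f(x) − E_bg[f] (efficiency), which the tests
assert; rankings use the mean absolute attribution. The filter loop
retrains on the top 30, 35, 40, 45, 50 ranked descriptors (capped and
logged when fewer exist) and selects the size with the highest LOO Q²,
ties to the smaller size; the selection criterion is configurable because
no single printed rule reproduces every published size choice.

**Hybrids.** The delta-learning model fits a base regressor (default
SVR), then fits each further layer (default one KRR layer) to the
training residuals of the stack so far; the prediction is the sum. With a
near-interpolating delta layer the training error vanishes by
construction — the training-set gain is expected and says nothing about
generalization, which is why held-out metrics are always reported
alongside. The mixture-of-experts fits experts independently and predicts
a fixed convex combination; weights are selected by seeded search over
the simplex (all unit vectors always included, so the fitted-set loss
never exceeds the best single expert's) against out-of-fold training
predictions — scoring raw training fits instead (available as an option)
would hand all weight to the most overfit expert. Weights are global; no
input-dependent gating.

## Synthetic data

Two generators make every stage testable without DFT runs.

* **Analytic excitations**: hole on a Gaussian at the origin, electron on
  one d bohr away; closed forms D = d, σ_λ = 1/(2√α),
  HDI = 100(α/π)^{3/2} are carried with the fixture, so the engine is
  checked against values it did not produce.
* **Feature tables** with the production 73-column manifest. Five named
  signal columns (S-ee, T-ee, soc, mw, eps — spanning all four blocks)
  are independent uniform latent factors; every other column is an
  "echo": a random signed mixture of the latents at correlation 0.7 plus
  idiosyncratic noise. This emulates the strong collinearity of real
  descriptor tables (S-/T-/D- triples, size measures, solvent constants)
  — with fully independent nuisance columns, kernel distances would be
  dominated by irrelevant dimensions and no method could recover the
  signal at n ≈ 136, which would make the fixture useless as a test of
  the pipeline rather than informative about it. The target is
  logistic(0.8·f) with f a stated smooth, mostly monotone function of the
  latents (linear terms plus small tanh and sine contributions, amplitude
  0.12) plus Gaussian noise at 5% of the signal SD. Tables are
  byte-identical under a fixed seed and record their generating
  conditions in the manifest.

What passing these tests shows: the protocol recovers a learnable planted
signal at realistic size and collinearity, and the attribution separates
signal columns from correlated echoes. What it does not show: performance
on real TMC photochemistry, where descriptor–target relationships are
noisier, nonstationary across metal centers, and not generated by any
smooth latent model.

**Evaluation sizes.** The recovery study trains on 122 rows (the
production training-set size) but evaluates on 214 independently drawn
rows of the same table (generator n = 336): a 14-row test split estimates
R² with a standard error near 0.1, too coarse to characterize model
quality, so the package reports held-out performance on the larger
evaluation set and uses the 90:10 split only where the protocol itself is
the object under test.

## Numerical choices and degenerate inputs

* Coincident centroids → H_CT := 0, flagged.
* Zero-integral densities, nonpositive excitation energies, unknown
  orbital indices, unknown solvents/metals → descriptive errors, never
  silent zeros; missing dipoles/SOC are carried as absent, not 0.
* Constant descriptor columns normalize to 0 with a warning; kernel
  ridge's own regularization floor handles singular kernel matrices.
* Ties in Shapley importance break by the model's descriptor order, so
  rankings are reproducible.

## Known limitations

* The engine consumes Cartesian s/p/d Gaussian orbitals (inline or
  Molden); f functions and effective-core-potential metadata are not
  supported — adequate for testing and for valence-dominated
  hole/electron analysis, not for reproducing production basis sets.
* The mlct definition is a documented stand-in; published values computed
  with other fragment schemes will differ.
* Synthetic tables are continuous surrogates; integer-valued descriptor
  blocks are not discretized.
* Exact numerical agreement with any particular quantum-chemistry
  post-processing tool is not claimable — grid construction differs —
  only convergence in grid level.
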