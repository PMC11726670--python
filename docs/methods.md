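# Methods

This note documents the models, numerical choices and limitations behind
`flexsol`, in the spirit of a software methods section.

## Physical model

A flexible molecule in solution is treated as an equilibrium of rapidly
exchanging rigid conformations. Observables are population-weighted
averages: a NOESY cross peak between proton groups *a* and *b* builds up at
rate σ_ab ∝ ⟨r_ab⁻⁶⟩, so time-averaged NMR data constrain the population
vector **w** over a candidate conformer pool but do not identify a single
structure. The deconvolution therefore fits **w** on the probability
simplex, never a geometry.

Assumptions inherited from this model:

* **Fast exchange** on the chemical-shift timescale; slow-exchanging
  systems (distinct sub-spectra) are out of scope.
* **Initial-rate regime** for build-ups: intensity linear in mixing time,
  no spin diffusion or relaxation-matrix treatment.
* **Pool completeness**: the fit can only redistribute weight over
  conformers it is given. The completeness probability
  `1 − (1 − 1/N)^M` quantifies search coverage but cannot detect a missing
  basin.

## Restraint generation

Cross peaks are normalized symmetrically against both diagonal peaks,
`I = sign(c_ab·c_ba)·sqrt(|c_ab·c_ba|/(d_a·d_b))`. Peaks visible on one
side of the diagonal only can be normalized as `c_ab²` via a flag; this is
a documented deviation from the symmetric default, not silently applied.

The build-up regression is **constrained through the origin** (zero NOE at
zero mixing time). R² is reported against that origin-constrained model
with the total sum of squares about the mean; an uncentered definition is
selectable. Acceptance requires ≥ 3 mixing times and R² ≥ 0.91 on both the
pair and the reference fit — the filter is enforced exactly, and rejected
restraints carry their reason. Negative normalized intensities survive
fitting but are rejected at the distance step (σ ≤ 0 has no distance).

Distances use `r_ab = 1.78 Å · (σ_ref/σ_ab)^(1/6)` with geminal methylene
protons as reference. The sixth root makes distances robust: 5%
multiplicative intensity noise perturbs distances by only ~0.8%.

³J(HH) couplings are inverted through a Karplus curve
`³J(θ) = A·cos²θ + B·cosθ + C` solved in closed form as a quadratic in
cos θ. **No coefficient set is shipped as default**: published sets vary by
substituent electronegativity, so the triple is a required input, and a
coupling outside the curve's attainable range is an explicit error naming
that range.

## Deconvolution

Objective:

    SSD(w) = Σ_dist ((d_calc − d_exp)/u_d)² + λ·Σ_dih (Δθ/u_θ)²,
    w ≥ 0, Σw = 1

* Within a conformer, CH2/CH3 groups are r⁻⁶ pseudo-atom averages over all
  inter-group proton pairs (reducing to the standard two- and three-site
  formulas).
* Across conformers the default is the NOE-consistent r⁻⁶ average
  `(Σ wᵢ rᵢ⁻⁶)^(−1/6)`; linear averaging is available behind a flag and
  covered by tests. The r⁻⁶ choice is the physically motivated one for
  distances derived from NOE intensities.
* Uncertainties default to u_d = 10% of the experimental distance and
  u_θ = 20°, with λ = 1; all three are configurable and echoed in reports.
* Optimizer: SLSQP on the simplex, 25 starts — the uniform vector, every
  vertex, and seeded Dirichlet draws. Vertex+uniform starts are
  permutation-symmetric, which keeps the fit permutation-equivariant in
  practice (tested to 1e-4). Weights below 1% are zeroed and the fit re-run
  once over the surviving support; the refit is only kept if the objective
  does not increase.
* Conformers indistinguishable under every restraint are detected by
  fingerprinting the back-calculated restraint matrix and reported as
  non-identifiable groups instead of pretending their weight split means
  anything.

Validation mirrors standard practice: multiplicative uniform noise
(`d → d·(1+U(−f,f))`, per restraint, per trial, seeded) with per-conformer
weight statistics, and leave-one-out jackknifing with an influence
threshold of 0.10 on any weight. Both 5% and 10% noise levels are
reasonable; the level is a parameter, with 5% used in the acceptance runs.

## Descriptors

* **Rgyr** is mass-weighted over all atoms (standard atomic weights); an
  unweighted heavy-atom mode exists for sensitivity analysis.
* **SASA** is Shrake–Rupley with Bondi radii, probe 1.4 Å, and 960 points
  per atom placed on a deterministic golden-section spiral — no RNG, so
  areas are bit-for-bit reproducible at fixed point count. Accuracy at 960
  points: ≤ 0.5% against the isolated-sphere closed form and ≤ 1% against
  the analytic two-sphere formula (both tested).
* **SA 3D PSA** sums accessible area over the explicit polar-atom rule: O,
  N, and H bonded to O/N. A charge-threshold selection rule sometimes used
  in visualization tools is deliberately not implemented: it depends on an
  unspecified charge model and is not reproducible; the fragment rule is.
  Per-fragment PSA uses the POI/linker/E3 partition, defined by the
  user-designated linker atoms whose removal must split the heavy-atom
  graph in exactly two.
* **Interactions** are detected with explicit geometric criteria
  (defaults: H···A ≤ 2.5 Å and ∠DHA ≥ 120° with ≥ 3 bonds separation for
  hydrogen bonds; ring-centroid ≤ 5.5 Å with interplane angle ≤ 30°
  face-to-face or 60–90° edge-to-face for π–π; H···centroid ≤ 3.5 Å,
  approach ≥ 120°, lateral offset ≤ 1.5× circumradius for NH–π). The counts
  are reproducible and criterion-stamped; they are not claimed to equal
  counts from any closed-source tool with undisclosed thresholds. Sulfur is
  not an acceptor. Aromaticity comes from file flags when present, else
  from perception of planar 5/6-rings of sp2-compatible atoms
  (≤ 3 connections, out-of-plane RMS ≤ 0.1 Å).

## Redundancy elimination

Greedy leader clustering in input order on the heavy-atom RMSD after Kabsch
superposition (superposition is assumed, configurable, since the upstream
convention is not universal). Because energies are not modeled, cluster
representatives depend on input order — pools sorted by energy upstream
retain their lowest-energy leaders. The default 3.0 Å cutoff is sized for
~1000 Da degraders; the synthetic fixtures use 1.5 Å because the generated
molecule is roughly half that size.

## Synthetic ground truth

The generator emulates the *shape* of a real study, not its chemistry:

* a three-part molecule (methylated benzamide "POI ligand", an eight-atom
  amide/ether linker, a thiazole "E3 ligand", ~48 atoms with explicit H)
  built from a SMILES template and embedded by distance geometry (ETKDG) —
  rule-based, seeded, no force field;
* conformer pools by seeded gauche/anti torsion draws (±20° jitter) about
  rotatable bonds with a 0.8 Å clash filter, anchored by an all-anti
  extended conformer and resampled (bounded) until the pool spans ≥ 2 Å in
  Rgyr;
* NOESY tables simulated by inverting the pipeline's own equations from a
  hidden sparse population vector (default 0.4/0.3/0.2/0.1 over 10
  conformers, 30 restraints, mixing times 100–700 ms, reference rate
  0.02 s⁻¹), with seeded multiplicative noise;
* a folded conformer with one planted hydrogen bond, π–π stack and NH–π
  contact, constructed by rigidly re-posing the E3 half against three
  geometric targets (6-dof Nelder–Mead) and rebuilding the linker along an
  arc with plausible bond lengths.

What passing on synthetic data does **not** show: recovery under real
spectral artifacts (overlap, spin diffusion, baseline), force-field-quality
geometries, or pools whose true conformer is absent. The simulated noise
model (multiplicative uniform on intensities) matches the validation
perturbation, which makes the noise-stability test a consistency check
rather than an instrument model.

## Numerical conventions and edge cases

* Mixing times are seconds internally; table readers accept milliseconds.
* Proton groups in tables are 1-based `+`-joined atom indices ("17+18").
* Monoisotopic masses use most-abundant-isotope masses; [M+H]+ adds
  1.00728 Da (electron mass neglected, ≤ 0.0006 Da effect); printed HRMS
  formulas that already include the proton are handled via a flag.
* Permeability class bins are half-open — [0,40) H, [40,100] M–H,
  (100,200] M–L, (200,∞) L — so every positive ratio maps to exactly one
  class; ratios are reported to 3 significant figures. Outer-limit gating
  is inclusive (a value exactly at the limit is within).
* Degenerate inputs fail loudly: empty ensembles, inconsistent atom
  ordering (the offending record is named), zero diagonals, all-zero
  build-ups, non-positive distances, linker sets that do not bisect the
  molecule.
* Structures without explicit hydrogens are rejected by H-dependent
  operations (SASA/PSA, hydrogen-bond detection) rather than guessing
  positions.

## Problem sizes

Default test and acceptance runs use a 10-conformer pool, 30 restraints,
25 optimizer starts and 20 noise trials — enough to make the deconvolution
well-posed (restraint count ≳ 3× the nonzero weights) while keeping a full
run in seconds on one core. Larger pools (the hundreds of conformers
typical after redundancy elimination) scale linearly in the restraint
matrix and are limited mainly by the SLSQP dimension.
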