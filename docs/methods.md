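# Methods

This note documents the models behind `fibrilmech`, the parameters that
matter, what the synthetic generator does and does not emulate, and the
numerical choices made where the design was open.

## 1. Quasi-harmonic analysis

An equilibrated fibril fluctuating about a mean structure is treated as
an effective harmonic system. With Cα coordinates `r(t)` (3N-vector, Å)
the fluctuation (covariance) matrix is

    Q = ⟨ (r − ⟨r⟩) ⊗ (r − ⟨r⟩) ⟩        (3N × 3N, Å²)

accumulated over frames after iterative least-squares superposition of
every frame onto the running mean structure (Kabsch rotations, repeated
until the mean is stationary; 50-iteration cap). Alignment removes rigid
diffusion, which would otherwise swamp the internal modes; the aligned
covariance therefore has (up to round-off) six near-zero eigenvalues
spanning the rigid-body space. `align=False` is available for analyses
that keep rigid motion as explicit low-frequency modes.

Spectral decomposition `Q v_j = ξ_j v_j` (dense symmetric solver;
eigenvalues descending, eigenvector signs fixed so the
largest-magnitude component is positive) gives:

* stiffness matrix `K = k_B T Σ' ξ_j⁻¹ v_j v_jᵀ` (the sum excluding the
  `n_rigid` smallest-ξ modes; K and Q are mutual pseudo-inverses scaled
  by k_B T on that subspace);
* natural frequencies `ω_j = √(k_B T / (M_C ξ_j))`, i.e. each principal
  mode is an oscillator of mass `M_C` whose equipartition variance is
  ξ_j. `M_C` defaults to 12.011 Da (a carbon atom) for protein Cα
  trajectories and to the bead mass for synthetic beams; it is
  configurable because other mass conventions (mean residue mass) are
  equally defensible — it rescales all frequencies by a common factor
  and cancels in rigidity *ratios* but not absolute values;
* fluctuation budget `RMSF² = (1/N) Σ' ξ_j`, `RMSF(k)² = ξ_k/N`, and the
  dimensionless contribution `α_k = ξ_k / Σ' ξ_j` (sums to 1). A
  non-squared variant `RMSF(k)/RMSF` is available behind the
  `alpha_variant` config switch.

Defaults mirror the usual equilibrium-MD protocol: T = 300 K, discard
the first half of the trajectory, `n_rigid = 6`.

## 2. Continuum beam model

A fibril free in solution is modelled as a free-free Euler–Bernoulli
beam of length L, mass per length μ, density ρ = μ/A. Free-free
boundary conditions are the only choice consistent with six rigid-body
zero modes. Analytic modes:

* bending: `φ_n(x) = A_n[(cosh β_n x + cos β_n x) − σ_n(sinh β_n x + sin β_n x)]`,
  `β_n L = λ_n` the roots of `cos λ cosh λ = 1`
  (λ₁ = 4.7300407…, λ₂ = 7.8532046…, higher roots refined from the
  asymptote `(2n+1)π/2` by bracketed root-finding on `cos λ = sech λ`),
  `σ_n = (cosh λ_n − cos λ_n)/(sinh λ_n − sin λ_n)`,
  `ω_n = λ_n² √(E_B I/(μL⁴))`;
* torsion: `θ_n(x) = cos(nπx/L)`, `ω_n = (nπ/L)√(G_T/ρ)`;
* extension: `u_n(x) = cos(nπx/L)`, `ω_n = (nπ/L)√(E_X/ρ)`.

Because a fibril cross-section is anisotropic there are two bending
families; the plane with the smaller second moment (larger ξ at order 1)
is labelled *soft*. Inversion is the exact algebra:
`E_B I = ω² μ L⁴ / λ_n⁴`, `G_T = ρ(ωL/nπ)²`, `E_X = ρ(ωL/nπ)²`,
`l_p = E_B I / k_B T`. Rigidities (N·m²) are the assumption-free primary
output; moduli (Pa) additionally require a cross-section model:

* `fixed`: a declared w × h rectangle (A = wh, I = wh³/12 and w³h/12,
  J = I_y + I_z);
* `envelope`: per axial station, the convex hull of the atom centers
  inflated by an effective atomic radius (Minkowski sum with a disk,
  default 1.7 Å); area and the second-moment tensor are averaged over
  stations and diagonalized. Good to ~5% in area and ~10% in I for
  convex cross-sections sampled densely; it underestimates both for
  sparse atoms.

### Mode classification

Each principal mode is decomposed per axial station into two transverse
components, an axial component, and a tangential (twist) component,
then projected onto orthonormalized analytic shape bases (orders
1…`max_order`, default 4) and the six rigid-body vectors. The family
with the largest squared overlap wins; a best overlap below 0.5 is
labelled `mixed`. The frequency of the best order-1 mode per family is
inverted into that family's property. Near-degenerate eigenvalues from
different families (e.g. a high-order bending mode crossing the first
axial mode) mix in the principal decomposition; overlaps drop there but
order-1 modes, which carry the inversion, are well separated.

## 3. Conformational metrics

* **Superposition/RMSD**: Kabsch SVD with determinant correction
  (always a proper rotation).
* **Layer frames and twist**: each β-sheet layer gets a centroid and an
  in-plane principal axis (sign-chained between layers so anti-parallel
  stacks have well-defined twist). The inter-layer dihedral is the
  standard four-point torsion (cis = 0°, right-handed sign, (−180°, 180°])
  of (axis end j, centroid j, centroid j+1, axis end j+1). For an ideal
  built fibril it equals the construction twist to 10⁻⁶ deg.
* **Bending angle**: 180° minus the angle subtended at the mid-fibril
  layer centroid by the two terminal layer centroids (0° = straight).
  The literature is not specific here; the three-centroid definition is
  the simplest that is exact for the straight reference and it is the
  documented, configurable choice.
* **Order parameter**: the population variance (rad²) of the inter-layer
  dihedrals, computed two-pass on wrap-corrected deviations (identical
  to the plain variance away from ±180°). OP = 0 for uniform twist;
  OP > 0.07 flags a disordered, thermodynamically suspect stack. A
  circular-standard-deviation variant is available (`op_variant`).
* **Strands per pitch**: `strands_per_layer × round(360°/mean dihedral)`;
  10° twist with 2 strands per layer gives 72 strands per turn.
* **Hydrogen bonds**: geometric criterion D···A ≤ 3.5 Å and
  D–H···A ≥ 150° over backbone N–H donors and carbonyl O acceptors,
  with a distance-only N···O ≤ 3.2 Å fallback (logged) when the
  structure has no hydrogens; same-strand neighbours (|Δres| ≤ 1) are
  excluded. Cutoffs are conventional and configurable.
* **SASA**: Shrake–Rupley with a deterministic golden-spiral point set
  (default 960 points/atom, minimum 16), Bondi vdW radii, 1.4 Å water
  probe. Per-atom and total areas are returned; accuracy is limited by
  the point count (isolated-sphere closed form reproduced to <0.5% at
  960 points).
* **Nonpolar solvation**: `ΔG_np = γ·SASA + β` with
  γ = 0.00542 kcal/mol·Å², β = 0.92 kcal/mol. The electrostatic
  (Poisson–Boltzmann) and molecular-mechanics terms of a full MM-PBSA
  treatment are deliberately out of scope.

## 4. Synthetic data

### Zipper builder

An idealized cross-β geometry: layers of one strand per sheet stacked
with a 4.8 Å rise and a configurable per-layer twist about the fibril
axis; sheets 10 Å apart; Cα spacing 3.4 Å along the strand. The eight
polymorph classes set the strand-direction pattern: anti-aligned classes
reverse direction between sheets, anti-parallel hydrogen bonding
reverses it between successive layers within a sheet. With backbone
atoms enabled, each residue carries N, H, Cα, C, O placed so that the
ladder hydrogen bonds run parallel to the fibril axis with a 3.4 Å
donor–acceptor distance. This geometry is deliberately schematic: the
C=O offset (1.40 Å) is longer than a real carbonyl and N of residue i
sits laterally on top of O of residue i−1, a contact a real backbone
resolves by pleating. It is exact where it needs to be (twist, rise,
strand topology, H-bond ladder) and wrong where it does not matter for
the metrics it validates. Passing tests on built fibrils therefore
demonstrate correctness of the *measurement* operations, not realism of
β-sheet stereochemistry.

### Beam sampler

The generator stands in for equilibrium MD: a straight beam of
`n_beads` axial stations (default 20 over 12 nm), each carrying a
centerline bead and two tracer beads offset ±1 nm perpendicular to the
axis (torsion is invisible to a pure centerline, so twist is recorded as
tracer displacement). All beads share one mass (default 800 Da, giving
a realistic fibril line density of ~6.6×10⁻¹⁵ kg/m and, with the
default 3 nm × 2 nm section, a protein-like density of ~1100 kg/m³).

Displacement fields for each analytic mode are sampled at the stations,
projected free of the six rigid-body vectors, and QR-orthonormalized in
family order (cross-family overlaps vanish by symmetry, so this only
removes the within-family non-orthogonality of discretely sampled
shapes). Each frame draws every modal amplitude independently from the
equipartition Gaussian `Var(q_n) = k_B T/(m ω_n²)` with m the bead mass
— with unit-norm equal-mass modes the modal mass *is* the bead mass, so
the quasi-harmonic frequency formula is the exact inverse of the
sampling distribution and parameter recovery is well-posed. Frequencies
come from the analytic formulas with the declared rigidities
(defaults: soft 1×10⁻²⁸ N·m², stiff 2×10⁻²⁸ N·m², G_T·J = 1.3×10⁻²⁷ N·m²
and E_X·A = 3×10⁻⁹ N, i.e. G_T = 0.2 GPa and E_X = 0.5 GPa — the
order-of-magnitude regime reported for short fibrils). An isotropic
Gaussian background of 0.3 Å rms (scaling as √(T/300 K)) stands in for
the many unresolved high-frequency modes of a real fibril, so that every
non-rigid direction carries variance; it biases the order-1 modal
variances by <1%. Optional per-frame rigid translation/rotation noise
emulates imperfectly removed global motion. Draw order is fixed and
documented; a seed fully determines the trajectory.

What the generator does **not** emulate: anharmonicity, mode coupling,
solvent damping and time correlation (frames are independent draws, so
autocorrelation-based analyses cannot be tested against it), sequence
effects, and finite-temperature structural drift. Recovery tests
therefore validate the estimator chain under the harmonic model the
analysis itself assumes — they bound implementation error, not model
error on real MD data.

### Study conditions for validation

Parameter recovery runs at 20 stations, 5000 frames, 300 K, fixed seed;
the achieved errors are ~0.1–1% for bending rigidities and ~1–4% for
G_T/E_X (dominated by finite-sample variance of the covariance, ~√(2/F)
per eigenvalue). Tolerances asserted in the tests are 10% (bending) and
15% (torsion/axial). The full recovery, including sampling, runs in
well under half a minute on one CPU.

## 5. Numerical choices and degenerate inputs

* Roots of the free-free characteristic equation via bracketed Brent on
  `cos λ − sech λ` (overflow-free), xtol 10⁻¹⁴, cached.
* Eigensolver: dense `eigh` on the symmetrized matrix; asymmetry beyond
  10⁻⁸ (relative) is an error. Degenerate eigenvalues get a
  deterministic sign/tie-break (first-index largest component positive).
* Superposition of a near-planar set: reflection corrected by flipping
  the smallest singular direction; fewer than 3 atoms is an error.
* Layer with all atoms coincident → "zero-length axis" geometry error;
  fibrils need ≥2 layers for twist, ≥3 for a bending angle.
* Principal-axis detection requires the largest second moment to exceed
  the next by 1.5×; spherical mass distributions are rejected rather
  than silently assigned an axis.
* PDB I/O through biotite; the builder stores the layer index in the
  B-factor column (recovered when the column is non-negative integers).
  Insertion codes are rejected. XYZ round-trips at the printed 10⁻³ Å.
* Windowing: `discard_fraction` then `stride`; empty result is an
  error; the time-per-frame metadata is scaled by the stride.

## 6. Known limitations

* Euler–Bernoulli kinematics only: no shear deformation, so short,
  thick fibrils (length ≲ 10 × cross-section) get *apparent* rigidities
  that underestimate the material stiffness. A Timoshenko correction is
  out of scope.
* The quasi-harmonic mass convention (single `M_C`) makes absolute
  frequencies convention-dependent for heterogeneous-mass systems.
* The envelope cross-section is a convex proxy; concave or hollow
  sections are overestimated.
* `classify_modes` needs station resolution ≥ 2 points per half-wave of
  the highest order requested; with 20 stations, order 4 is safe.
* H-bond detection is purely geometric; no energy or orbital criterion.
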