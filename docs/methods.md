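# Methods

This note documents the models, conventions and numerical choices behind
`ffcondense`, and what the synthetic benchmarks do and do not demonstrate.

## Units and conventions

Internal units are Angstrom, radian, kJ/mol and elementary charge; file
ingest converts Bohr → Å, Hartree → kJ/mol, kcal/mol → kJ/mol and degrees →
radians through a tagged-unit registry (CODATA factors).  Atom indices are
0-based internally; MOL2/SDF 1-based indices are converted at the boundary.
Dihedrals follow the IUPAC sign convention via the atan2 construction
(cis = 0, trans = π); the signed dihedral is invariant under traversing the
chain backwards and negates under mirror reflection.

Internal coordinates are listed once each in a canonical direction: angles
`(i,j,k)` with `i < k`; propers keep the orientation whose `(j,k,i,l)`
comparison tuple is lexicographically smallest; impropers store
`(center, n1, n2, n3)` with neighbors ascending.  Atom-type tuples in the
condensation table are canonicalized with the same rules (bond sorted, angle
ends sorted, proper vs. its reverse, improper neighbors sorted); when an
angle key is matched in the reversed orientation, the orientation-sensitive
stretch–bend parameters (`k_sb_ijk`/`k_sb_kji`, `r_ij0`/`r_jk0`) are swapped
on assignment.

## Energy models

**Class I.** Harmonic bond and angle terms, a cosine-series proper torsion
(up to n = 6), point-charge Coulomb and 12-6 Lennard-Jones with
Lorentz–Berthelot combination.  1-2 and 1-3 pairs are excluded; 1-4 pairs
are scaled by 0.5 (vdW) and 0.8333 (Coulomb) by default.

**Class II (MMFF94-style).** Quartic bond stretch
`k_r/2 Δr²(1 + c_s Δr + 7/12 c_s² Δr²)`, cubic bend
`k_θ/2 Δθ²(1 + c_b Δθ)`, stretch–bend coupling, the three-fold phased
torsion `k₁(1+cos Δφ) + k₂(1−cos 2Δφ) + k₃(1+cos 3Δφ)` (the phase φ₀ is kept
even though canonical MMFF94 has none), a harmonic Wilson out-of-plane term,
buffered Coulomb `k_C q_i q_j/(r+δ)` with δ = 0.05 Å, and the buffered 14-7
van der Waals form.  Default 1-4 scalings: 1.0 (vdW), 0.75 (Coulomb).  An
alternative "squared-polynomial" stretch reading,
`k_r/2 Δr²(1 + c_s Δr + 7/12 c_s Δr)²`, is selectable via
`EngineConfig(stretch_form="literal")` for comparison; the quartic expansion is
the default because it is the established MMFF94 form and the squared
variant is dimensionally inconsistent in its c_s powers.

**Out-of-plane term.** Each improper center `(j; i,k,l)` (a trigonal atom
with exactly three neighbors, detected by element + neighbor-count patterns;
defaults: N:3, C:3) contributes the sum of the three Wilson wag angles —
each neighbor measured out of the plane of the center and the other two —
with a single force constant, `Σ k_oop/2 χ²`.  This is the MMFF94
convention; an improper-dihedral coordinate would be an alternative and
gives slightly different curvature away from planarity.

**A note on the buffered 14-7 minimum.** With buffering constants 0.07 and
0.12 the buffered 14-7 takes the value −ε at r = r* exactly, but its true
stationary point is at r = 0.9961827 r* with depth 1.0005648 ε (exact root
of the derivative).  The common statement "minimum −ε at r*" therefore holds
to ~0.4 % in position and ~0.06 % in depth.  The optimizer tests target the
exact stationary point.

**Coulomb constant.** k_C defaults to 138.935458 kJ·mol⁻¹·Å·e⁻²
(1/4πε₀ in MD units); it is configurable, as are δ and all scalings, because
deployed screening engines embed their own values.

**Gradients.** All bonded terms and both non-bonded forms have analytic
Cartesian derivatives assembled by the chain rule through the internal
coordinates (distance, angle, dihedral, Wilson angle).  Near-linear angles
are regularized with a 10⁻⁸ guard in the sin θ denominators.  Internal terms
exert zero net force and zero net torque; the suite checks agreement with
central finite differences (step 10⁻⁵ Å) to < 10⁻⁶ relative error and
rigid-motion invariance of the energy to < 10⁻⁹ kJ/mol.

## Charge equilibration

Charges minimize `Σᵢ (eᵢqᵢ + sᵢ/2 qᵢ²)` subject to `Σqᵢ = Q`, the
second-order per-atom expansion with electronegativity e and hardness s
(no Coulomb cross-terms — the simple expansion of the upstream protocol).
The Lagrange solution is closed-form; all sᵢ > 0 is required (convexity) and
the constraint holds to machine precision.  Conformation-dependent charges
and polarizability are out of scope.

## Condensation

Records `(molecule, category, atom-type tuple, parameter name, value, unit)`
are pooled per canonical key after unit normalization; records with wrong
tuple arity or non-finite values are counted and skipped, while a unit
*dimension* clash within one parameter name is a hard error.  Statistics:

* **mean** (default — the representative value used throughout),
* **median** (midpoint convention for even n),
* **mode** — midpoint of the most populated Freedman–Diaconis histogram bin,
  ties broken toward the lower bin; degenerate IQR falls back to Sturges
  binning.  Delta distributions short-circuit to the exact common value for
  all three statistics, so a single-molecule table reproduces that
  molecule's parameters bitwise.

Only bonded categories (bond, angle, proper, improper) are condensed;
non-bonded per-atom parameters pass through from their source unchanged.  A
per-key minimum-count threshold (default 1) suppresses sparsely observed
keys.  Tables serialize to CSV plus a JSON metadata sidecar recording the
statistic, source and creation time; duplicate key rows and version
mismatches are rejected on read.

## Assignment and the drop policy

Every enumerated interaction is keyed by its atoms' types and filled from
the table.  A missing key — or a key missing any required parameter name
("partial entry", logged with its own reason) — drops the whole interaction:
it is recorded in the `AssignmentReport` and contributes nothing to the
energy.  There is deliberately no step-down/wildcard fallback; per category,
assigned + dropped always equals the enumerated count.  Class I torsions
require φ₀ and at least one k_n (absent orders are zero); Class II torsions
require k₁,k₂,k₃,φ₀.  `assign_direct` builds a single-molecule table from
that molecule's own records and assigns from it, which makes the
condensed ≡ direct equivalence in the σ = 0 limit structural rather than
approximate.  The `assign` CLI emits a bonded-only parameter set; non-bonded
values are attached through the API (`NonbondedParams`), matching the scope
of the condensation table.

## Optimization

L-BFGS (memory 10) with analytic gradients; if it terminates without meeting
the gradient tolerance, full-memory BFGS restarts from the best point seen
and the result is flagged `bfgs_fallback`.  Convergence means gradient
infinity-norm ≤ 10⁻⁵ kJ·mol⁻¹·Å⁻¹ (default; the relative-energy-change
floor of 10⁻¹⁰ only stops the line search).  The iteration cap is 2000; the
returned conformer is always the best-energy point observed, so the final
energy never exceeds the initial one, and an unconverged run returns a
flagged result rather than raising.  These thresholds are package defaults
chosen for small drug-like ligands; flat wells (e.g. the buffered 14-7 pair)
need tighter tolerances to localize the minimum below 10⁻⁶ Å, and the tests
set them accordingly.  No global search or multi-start is performed — the
evaluation design deliberately separates force-field accuracy from
global-minimum search.

## Evaluation

RMSD is computed over heavy atoms by default after Kabsch superposition
(SVD with reflection correction).  No graph-automorphism symmetry correction
is applied: for molecules with topologically equivalent atoms (e.g. methyl
rotors) the reported RMSD is an upper bound.  TFD is
`Σ wᵢ·min(|Δφᵢ|, 2π−|Δφᵢ|)/π / Σ wᵢ` over one representative torsion per
rotatable bond (non-ring, both ends non-terminal; lexicographically smallest
proper per bond), uniform weights by default with a pluggable weight
function; molecules without rotatable torsions return a flagged
defined-empty 0.  Against a multi-minimum reference set the nearest
reference is selected independently per metric (ties to the lowest index),
reflecting that an optimizer may legitimately relax into a neighbouring
basin.  Cohort summaries report mean/median and empirical CDF curves.

## Synthetic data: what it shows and what it does not

The fixtures module emulates the upstream predictor: type-keyed true
parameter tables over a C/H/N/O toy set (diatomic, bent triatomic, ethane,
united-atom butane, a trigonal center; force constants and geometry on
common small-molecule force-field scales), with per-molecule records drawn
`Normal(true, σ)` under explicit seeds and no global random state.  Because
the truth is type-keyed, interactions sharing a key share true values, so at
σ = 0 the condensed table must reproduce direct parametrization exactly —
the pipeline's delta-limit identity — and at σ > 0 the condensed-vs-direct
geometry deviation grows monotonically with σ.  The mini-typer is a fixture
convenience (element + neighbor count), not a chemical perception model.

Passing these benchmarks demonstrates the machinery — enumeration, grouping,
statistics, lookup, drop policy, gradients, optimization, metrics — is
correct and deterministic.  It does not demonstrate chemical accuracy on
real molecules: the toys lack conjugation, rings, heteroatom diversity and
conformational complexity, and the noise model is homoscedastic Gaussian
while real predictor distributions can be skewed or multimodal.  Benchmark
problem sizes (≤ 14 atoms, corpora of 50–200 molecules) keep the full suite
and the acceptance script within seconds on one CPU.

## Known limitations

* No periodic boundaries, cutoffs, Ewald, implicit solvent or
  polarizability; single connected molecules only.
* Atom typing is external (file column, sidecar, or the fixture
  mini-typer); full 100-type perception is a pluggable interface, not
  implemented here.
* No SMILES → 3D embedding; starting coordinates come from the input file.
* RMSD symmetry correction and the topological-distance TFD weighting of the
  original fingerprint scheme are not implemented (uniform weights default).
* Torsion records are one per cosine order (`k_phi_n`); vector-valued
  records are not supported.
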