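# Methods

This note documents the models, algorithms and numerical choices behind
`glycosurf`: a Gaussian-process Bayesian-optimization (BO) structure search
for flexible carbohydrate adsorbates on fcc(111) metal surfaces, with
surface-symmetry data augmentation, Kabsch deduplication, force-seeking
training-data curation, local relaxation, and a lightweight learned
surrogate potential that enables a cheap second search pass.

## Reduced coordinates

Global structure determination in full Cartesian space is intractable for
molecules of this size, so searches run in reduced coordinates:

* **Conformer mode.** One variable per hydroxyl torsion, two per glycosidic
  linkage (the φ = O5′–C1′–O4–C4 and ψ = C1′–O4–C4–C3 torsions), and a
  reduced two-torsion ring-flip coordinate per pyranose ring. This gives 6
  dimensions for β-D-xylose (4 OH + ring pair), 16 for 1,4-β-D-xylotetraose
  (10 OH + 3 φ/ψ pairs), 24 if the four ring flips are added, and 10 for
  xylose under the full one-coordinate-per-ring-atom parametrization (4 OH
  + 6). The full parametrization is supported by the dimensionality
  counter but not by the realizer; the reduced pair is the operational
  choice.
* **Adsorption mode.** The building-block approximation: a rigid conformer
  and a rigid slab, combined by 6 rigid-body coordinates
  (tx, ty, tz, α, β, γ). tx, ty range over one orthogonal surface cell
  (a = a_fcc/√2, b = a√3; 2.568 × 4.448 Å for Cu), tz is the height of the
  adsorbate geometric center above the top-layer plane, and (α, β, γ) are
  intrinsic z-y-z Euler angles about the geometric center. tx, ty, α, γ are
  periodic; β ∈ [0, π] and tz are bounded.

**Ring flip.** The two driven torsions are O5–C1–C2–C3 and C3–C4–C5–O5.
With all bond lengths and all template angles held exactly, a 6-ring with
two fixed torsions generically cannot close; the closure solver therefore
treats the two interior chain torsions plus small regularised perturbations
of the three interior ring angles as unknowns of a damped Gauss–Newton
iteration on the 3-D closure residual (tolerance 1e-4 Å, angle-perturbation
penalty 0.05). Bond lengths are exact by construction (NeRF chain build);
substituent subtrees ride on local (prev, atom, next) frames. If closure
fails the point is reported as a realization failure and treated as a
high-energy configuration.

## Slab geometry

`nx × ny` counts atoms per layer directly (a 6×8×4 slab has 192 atoms;
with a 20-atom xylose this gives the 212-atom production system, and
14×16×4 + 71 gives 967). Note this differs from the common convention in
which an orthogonal (111) cell carries two atoms per layer; the atom-count
convention is what reproduces the production system sizes. Layers are
ABC-stacked at spacing a_fcc/√3 with offsets chosen so the *top* layer has
an atom exactly at the cell origin — the atop axis used by the symmetry
group. `ny` should be even for exact y-periodicity. Vacuum (60 Å default)
is split symmetrically; the bottom `n_frozen_layers` are frozen.

## Energy transformation

GP surrogates fit poorly when the dataset spans hundreds of eV of Pauli
repulsion. Configurations with any interatomic contact below 0.5 Å skip
the backend entirely and enter the dataset at a flat 5.0 eV placeholder;
relative energies above 1.0 eV are compressed to `1 + ln(E)` eV (natural
logarithm, which keeps the transform continuous at the threshold). The
transform is monotone, so the ranking of minima is unaffected.

The zero of relative energy is the energy of the relaxed isolated building
blocks (conformer + clean slab) at infinite separation, fixed once per
search so the transform is stable across iterations.

## Gaussian-process surrogate and acquisition

The kernel is a product over dimensions — squared-exponential for bounded
variables, the standard periodic kernel `exp(−2 sin²(π d/P)/ℓ²)` for
periodic ones — scaled by a signal variance, plus observation noise. The
prior mean is the mean of the transformed energies. Hyperparameters
maximise the log marginal likelihood (analytic gradient, multistart bounded
L-BFGS, seeded; jitter escalation 1e-8 → 1e-4 of the signal variance for
near-singular kernels). For noiseless toy objectives the noise can be
pinned (default 1e-6).

Acquisition is the exploratory lower confidence bound `μ − κσ` with
κ = 2.0. Pure LCB over-exploits the incumbent basin and maps only the
global well; since the goal is the set of low-energy minima, every third
iteration proposes the maximum-posterior-uncertainty point instead
(uncertainty interleave, configurable via `explore_interval`). Acquisition
and posterior-mean minimisation both use seeded Halton candidates (20·D
for proposals, 100·D for minima harvesting) screened in one vectorised
pass, with bounded L-BFGS polish of the best candidates (8 and 40 by
default); polishing every candidate would be redundant on the smooth GP
surface.

The loop starts from 5 Halton points and terminates when the
posterior-mean argmin has moved less than 1% of each dimension's range for
100 consecutive iterations (the production stall rule), or at the
iteration budget. Convergence compares argmin *location*, not value.

## Surface-symmetry augmentation

Every sampled 6-D adsorption observation is duplicated under
{identity, translation (a/2, b/2)} × {C3 rotations about the atop axis at
the cell origin}: five free copies per general-position point, with
coincident images removed. A C3 rotation about the lab z-axis composes
into the *first* intrinsic z-y-z Euler angle (α ± 120°) and rotates the
lateral center. The toy surface backend is exactly invariant under this
group (to machine precision), which the test suite verifies; augmentation
multiplies dataset rows without changing the set of sampled energies.

## Kabsch deduplication

Minima harvested from the surrogate are compared by minimum RMSD over an
optimal proper rotation + translation (Kabsch). Conformer-mode minima are
compared molecule-to-molecule; adsorption-mode minima are compared on the
full adsorbate+slab system, because any two placements of a *rigid*
conformer superpose to ~0 on their own. Deduplication is a greedy pass in
ascending energy with a 0.3 Å threshold (configurable; relaxed-basin RMSDs
in this regime are typically 0.1–0.6 Å). Where symmetry-equivalent
structures must be identified (workflow-closure comparisons), the RMSD is
minimised over the surface symmetry group first.

## Local relaxation

A damped BFGS with per-atom step cap 0.2 Å, energy-monotone backtracking,
first-update curvature scaling, and a steepest-descent reset when the
curvature along a step is negative (LJ/Morse tails). Convergence when the
largest unfrozen force component is below `fmax` (0.01 eV/Å default, 0.03
is a common relaxed setting for surrogate backends). Frozen atoms —
bottom slab layers, plus all substrate atoms under `fix_substrate` — move
exactly 0. The step count reported is the number of force evaluations
after the first, so an already-relaxed input costs 0 steps.

## Packaged empirical backends

These stand in for an electronic-structure engine at desk scale; any real
engine plugs in through the same calculator contract
(`evaluate(structure) → (energy, forces)` + `reference_energy`).

* **Intramolecular** (`ToyIntramolecular`): Lennard-Jones terms between
  atom pairs ≥ 4 bonds apart (per-element ε, σ; Lorentz–Berthelot mixing)
  plus a directional O–H···O hydrogen-bond well
  `−ε_hb cos²φ exp(−(r−r0)²/2w²)` (ε_hb = 0.2 eV, r0 = 1.9 Å, w = 0.3 Å,
  active for φ > 90°). Analytic forces; exactly invariant under rigid
  motion. Topology is fixed at construction from a reference geometry.
* **Molecule–surface** (`ToySurface`): pairwise adsorbate-atom/metal-atom
  Morse wells `D[(1−e^{−α(r−r0)})² − 1]` with a C¹ switching function
  `(1−(r/rc)²)²`, summed over substrate atoms within 4 Å (minimum image).
  Pair depths H 0.010, C 0.050, O 0.150 eV (oxygen binds the metal far
  more strongly, so orientation and site matter); α = 1.2 Å⁻¹, r0 = 2.3 Å.
  Because the energy depends only on distances to the periodic metal
  lattice, the half-cell translation and the C3 rotation about the atop
  axis are exact symmetries, and lateral corrugation (hollow > bridge >
  atop) emerges from the lattice geometry. Substrate reaction forces are
  dropped: the slab is rigid by construction.

What these backends do *not* emulate: electronic charge transfer,
image-charge screening, fcc/hcp hollow inequivalence beyond geometric
second-layer effects, or realistic conformational strain. Tests passing on
them demonstrate the correctness and closure of the *workflow* machinery,
not chemical accuracy for any real system.

## Learned surrogate potential

A deliberately simple stand-in for a production ML potential: per-atom
Gaussian radial-distribution descriptors per (center element, neighbour
element) channel (8 Gaussians from 0.6 Å to the 3.5 Å cutoff, C¹ switch),
a linear per-atom energy model with per-element offsets, and a joint ridge
least-squares fit of energies and force components. The two loss blocks
are normalised by their own row counts and summed 1:1, so thousands of
force rows cannot swamp the energy scale. Forces are the exact analytic
negative gradient of the predicted energy, so the model serves as a search
and relaxation backend through the calculator contract. Frames are split
90/10 train/validation by a seeded shuffle; energy (eV/atom) and force
(eV/Å) MAEs for both splits are reported. Serialization is a documented
JSON schema.

## Two-pass workflow and its validation stage

The end-to-end driver (`run_two_pass`) mirrors the production workflow at
desk scale:

1. first-pass BO on the toy backend (80 iterations default, with symmetry
   augmentation);
2. harvest + dedup; full relaxation of the best minima (trajectories join
   the training set);
3. a force-seeking BO run — the BO objective becomes the negative largest
   force component — whose high-force frames guard the learned potential
   against spurious extrapolation minima;
4. training of the surrogate potential on all sampled frames;
5. second-pass BO with the learned potential as backend, harvested the
   same way, *plus* a direct low-discrepancy scan + descent on the
   potential itself (the potential is cheap enough to scan exhaustively —
   the capability the second pass exists to exploit);
6. engine validation: the top candidates of each pass are relaxed
   (rigid-body) on the toy backend and re-ranked by its energies before a
   global minimum is declared — the analogue of relaxing every predicted
   minimum with the expensive engine.

The validation stage is what makes the closure check well-posed: (111)
adsorption landscapes have families of minima separated by only a few meV
(e.g. registry shifts), far below the resolution of any cheap surrogate,
and the deterministic engine-level ranking resolves them.

The packaged closure system is a rigid 10-atom diol on a 4×4×2 slab
patch. Its backbone torsion (100°) makes the O···O separation (2.57 Å)
commensurate with the hollow-site spacing — a lock-and-key arrangement
with an energetically distinct global registry — and its inequivalent
hydroxyl torsions remove all internal molecular symmetry, so no two
placements are exactly degenerate under an atom permutation (which an
ordered-correspondence Kabsch comparison cannot see). The z window is
2–7 Å, the production 3–12 Å window rescaled to the toy potential's length
scales. Xylose and xylotetraose templates drive the conformer-mode and
accounting paths; their adsorption landscapes are searchable with the same
machinery but their basin structure at desk budgets is too degenerate for
a sub-0.3 Å closure assertion, which is why the closure system is the
diol.

## Problem sizes

Defaults are chosen so a full test run (including the two-pass closure)
completes on one CPU core in minutes: 2-D planted-landscape searches use
up to 150 evaluations; adsorption searches 60–100 iterations (plus 5
initial points, ×6 symmetry augmentation in the GP); the force-seeking run
40 iterations; the learned potential trains on ~200 frames; validation
relaxes ~20 candidates per pass.

## Known limitations

* The ring-closure solver relaxes interior ring angles slightly (regularised),
  so ring-flip geometries are idealized rather than strain-minimised.
* The learned potential is two-body by construction; it cannot represent
  angular binding preferences and is not intended to approach
  production-potential accuracy.
* Kabsch comparison assumes a consistent atom ordering; permutational
  near-degeneracies of symmetric adsorbates must be avoided at the fixture
  level (the packaged diol does).
* The toy backends' parameters are plausible in scale but not fitted to
  any material; no chemical conclusions should be drawn from their minima.
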