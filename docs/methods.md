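# Methods

## Problem and representation

`dgfold` reconstructs a protein's three-dimensional Cα trace from
bounded inter-residue distance restraints.  The chain is represented
either in Cartesian coordinates (an L×3 array, Å) or in internal
coordinates: L−1 virtual bond lengths (fixed at 3.8 Å, the standard
trans-peptide Cα–Cα distance, for chains the package builds itself;
carried as measured for chains read from PDB files so imported
structures round-trip exactly), L−2 pseudo planar angles θ in
(0°, 180°), and L−3 pseudo dihedral angles τ in (−180°, 180°] with
the right-handed IUPAC sign convention (a right-handed α-helix has
τ ≈ +50°).  Chain construction from internal coordinates uses the
standard NeRF recurrence in a canonical frame (residue 0 at the
origin, residue 1 on +x, residue 2 in the xy-plane, y > 0), making
conversions deterministic and bitwise reproducible.  Angles at API
boundaries are degrees; radians internally.  Collinear triples
(θ within 10⁻⁶ rad of 0 or 180°) are rejected because τ is undefined
there.

## Objective

Each restraint (i, j, lower, upper, confidence) contributes a
flat-bottom squared hinge

    v(d) = max(0, lower − d) + max(0, d − upper),     E_ij = w · v(d)²

which is zero anywhere inside the bounds and grows quadratically
outside; this is the simplest smooth penalty consistent with
floor/ceiling bound semantics.  Confidence weighting (w = confidence)
is off by default — the bundled study uses binary-quality bounds —
and available as a flag.  A harmonic connectivity term
k_b (d_{i,i+1} − 3.8)², k_b = 10, keeps the chain intact during
Cartesian optimization; it is identically zero for conformations
built from fixed-bond internal coordinates.  At d = 0 the hinge is
not differentiable; the implementation uses the zero subgradient
there and logs a warning.  The energy is invariant under rigid
motions *and* reflections — distance data cannot see handedness —
which is why chirality is handled by a separate post-processing step.

Two optimizer-only modifications of this objective are deliberate
design choices:

* **Per-residue normalization.**  The optimizers minimize E/L rather
  than E.  The per-atom gradient is then of order "mean violation"
  independent of restraint count, which places the documented step
  sizes (0.005 coarse, 0.0001 fine polish, 65,000 iterations each)
  comfortably inside the stability region of fixed-step steepest
  descent, both from the extended state and near the minimum.  With
  unnormalized sums the same steps diverge from extended starts; with
  per-restraint means they are ~30× below the useful range and 195,000
  iterations do not converge.
* **Bound centering.**  Within 1 Å-wide bounds the hinge is exactly
  flat, so every pair may individually sit anywhere in its bound;
  this slack accumulates along extended, rod-like folds (an ideal
  30-residue helix reconstructed from floor/ceil bounds plateaus near
  TM ≈ 0.88 even at essentially zero hinge energy).  The optimizer
  objective therefore adds ε·w·(d − midpoint)² with ε = 0.05,
  preferring the central solution of the feasible region — the
  natural point estimate when the true distance is known only to lie
  between the bounds.  ε is small enough that hinge satisfaction
  always dominates; the σ = 4 Å noise results are unchanged by the
  term (TM 0.844 with and without, same seed), so it does not inflate
  the noise study.  The public `restraint_energy`/`restraint_gradient`
  API reports the pure hinge + connectivity objective; `centering`
  is a config field on both optimizers (set 0 to disable).

## Optimizers

**Cartesian gradient descent** iterates x ← x − η∇E with fixed step η
(default 0.005, 65,000 iterations) on the analytic gradient.  It is
deterministic, records the objective every `report_every` iterations,
polls an optional stop signal between report blocks, and aborts with
a diagnostic if the energy exceeds 10¹² or becomes non-finite.

**Simulated annealing** operates in angular space, where connectivity
is exact by construction.  Each move perturbs one uniformly chosen
angle: a Gaussian step of width 8°, or for dihedrals a sign flip
τ → −τ with probability 0.2 or a fresh uniform draw with probability
0.1.  θ proposals are clamped into (1°, 179°), τ wrapped into
(−180°, 180°].  Acceptance is the Metropolis rule on the per-residue
restraint objective under a geometric temperature schedule from 300
down to 0.03 (per-residue energy units) over 65,000 iterations.
Three further ingredients, each adopted because the plain single-angle
sampler demonstrably stalls:

* *Sign-flip and fresh-draw moves* escape locally mirrored segments —
  sub-chains whose handedness is inverted satisfy all local bounds
  and are separated from the correct basin by a barrier that small
  Gaussian steps essentially never cross.
* *Periodic relaxation*: every 2,000 moves, 300 iterations of
  Cartesian gradient descent relax the current state; the relaxed
  state is kept only if it lowers the restraint energy (a
  basin-hopping flavour that combines the samplers' global moves with
  the local minimizer's precision).
* *Secondary-structure-guided proposals*: when a secondary structure
  is supplied, moves on angles lying entirely inside one helix or
  strand segment draw, with probability 0.5, from a Gaussian around
  the ideal pseudo-angles (θ, τ) = (91°, +50°) for helix and
  (120°, −170°) for strand.  This is the fragment-free analogue of
  fragment-assembly moves: the secondary structure biases *sampling*
  only — every proposal still passes through the Metropolis filter on
  the restraint energy, and the energy itself never sees the
  secondary structure.  Chains without secondary structure are
  sampled exactly as before.  Guidance also breaks the global mirror
  symmetry in favour of the right-handed fold.
* A deterministic *greedy quench* ends the stage: repeated per-angle
  sweeps over a fixed candidate list (±2°, ±5°, ±10°, the sign flip,
  and the secondary-structure ideal where defined), accepting strict
  improvements, until a sweep changes nothing (at most 25 sweeps).

Annealing is bitwise reproducible for a fixed seed: all randomness
flows from one `numpy` Generator, and the quench and relaxations are
deterministic.

**Cascades** chain stages, threading the conformation; the start
defaults to the unfolded extended state (θ = 135°, τ = 180° zig-zag,
which avoids the collinear θ = 180° degeneracy).  Two presets are
provided: `case-study` = one annealing run (seed 0 by default)
followed by three repeated gradient-descent runs at default
parameters, and `benchmark` = two gradient-descent runs of 65,000
iterations with steps 0.005 then 0.0001.  Stage parameters are fully
configurable programmatically or through a small YAML schema.

## Chirality correction

Because the objective is reflection-invariant, the optimizer lands in
either hand.  For every window of four consecutive residues lying
entirely within one helix or one strand segment, the handedness cost
adds the wrapped angular distance |τ − τ_ref| (τ_ref = +50° for H,
−170° for E — the canonical Cα pseudo-dihedrals of the right-handed
helix and right-twisted strand).  The lower-cost of {model, mirror}
is returned; ties keep the input, making the fix idempotent.  Windows
spanning two segments are excluded.  Only the global mirror is
considered; per-segment (local) mirror repair is out of scope — the
annealer's flip moves handle local defects during optimization
instead.

## Restraint generation and noise protocol

Near-native restraints take floor/ceiling of the true distances
(bounds within 1 Å; exact integers give zero-width bounds),
confidence 1, over all pairs by default (reconstruction mode) or only
pairs with |i − j| > 6.  The noise protocol forms the pool of pairs
with sequence separation > 6, selects round(level · pool) of them
uniformly without replacement (seeded), adds one N(0, σ²) draw per
selected pair to both matrix triangles (preserving symmetry), clamps
noisy distances from below at 3.8 Å (sub-bond targets are physically
impossible; the clamp count is available by comparing matrices), and
only then applies floor/ceiling.  Noise is injected before flooring,
matching the order "true distances → noise → bounds".  The emitted
restraint set defaults to the pool pairs; the bundled study passes
`min_separation=0` to emit all pairs while noising only the
long-range pool, i.e. the full noisy matrix is what the folding
engine sees.

## Scoring

TM-score is computed for equal-length traces (residue i ↔ residue i):
superpositions are seeded on contiguous fragments of length L, L/2,
L/4, L/8 (≥ 4) at every offset, each iteratively re-superposed on the
residues closer than max(d₀, 4.5 Å) until the aligned set stabilizes
(≤ 20 rounds), and the reported score is the maximum of
(1/L) Σ 1/(1 + (dᵢ/d₀)²) over all superpositions, with
d₀ = 1.24(L−15)^⅓ − 1.8, floored at 0.5 Å for L ≤ 21.  Superpositions
are proper rotations only (Kabsch via SVD with the determinant
correction), so a mirror fold scores strictly below its source.  RMSD
is the Kabsch-optimal all-residue value.

## Synthetic structures

The test suite and the bundled study use generated structures only:

* `make_helix(L)` — ideal right-handed Cα helix (θ = 91°, τ = +50°).
* `make_compact_chain(L, seed)` — a self-avoiding random chain grown
  residue by residue (θ ~ U[80°, 150°], τ ~ U(−180°, 180°]), redrawing
  any placement that brings non-bonded residues closer than 3.5 Å.
  These chains have no secondary structure and no handedness signal;
  they are *harder* folding targets than real proteins because their
  geometry is irregular.
* `make_alpha_beta_target(seed)` — a synthetic, deterministically
  generated compact 68-residue α/β protein (three helices and three
  strands joined by coils; radius of gyration ≈ 11 Å, clash-free).
  Helix/strand segments carry ideal pseudo-angles; coil angles are
  set by a seeded greedy search that compacts the chain.  It stands
  in for a small experimentally determined α/β protein in the
  robustness study.

What these fixtures do not emulate: real β-sheets (generated strands
are not hydrogen-bond paired), loop ensembles, side-chain packing, or
experimental coordinate error.  Passing the study on them shows the
optimizer recovers structure from distance information of a given
quality; it does not certify performance on predicted distance maps
of real proteins.

## Study design and problem sizes

The bundled robustness study (tests and `scripts/acceptance.py`)
uses: the 68-residue synthetic target folded with the case-study
cascade from near-native bounds; the noise ladder σ ∈ {1, 2, 4} Å ×
levels {50%, 100%} with 5 noise realizations per condition (medians
reported); monotone degradation on L = 50 compact chains at level
100% across σ ∈ {0, 1, 2, 4} (means ± s.e. over 5 seeds); and
parameter recovery on 10 compact chains with L spanning 30–60.  These
sizes give stable medians while keeping a full study run in the
minutes range on one CPU.  For chains without secondary structure the
restraints are exactly reflection-invariant, so recovery scores a
fold against the better of the native and its mirror; with secondary
structure available the chirality fix resolves the hand and no mirror
maximum is taken.

## Numerical choices and degenerate inputs

* Collinearity tolerance 10⁻⁶ rad; θ clamps at (1°, 179°) during
  annealing keep τ well-defined.
* Kabsch uses SVD with a determinant sign correction; reflections are
  never permitted.
* Ties in the chirality fix keep the original (idempotence).
* Coincident restrained pairs get a zero subgradient plus a logged
  warning rather than NaN propagation.
* Gradient descent aborts with a diagnostic (iteration index, advice
  to reduce the step) when the objective exceeds 10¹² or leaves the
  float range.
* Duplicate RR records: last one wins, with a warning.  RR records
  may have 4 or 5 columns (confidence defaults to 1).  PDB reading
  takes the first model, first alternate location, renumbers residues
  1..L, and treats nonstandard residues as 'X'.
* Chains of ≥ 500 residues trigger a soft warning (the engine is
  intended for small/medium single domains), never an error.

## Known limitations

* Distance bounds of finite width bound the attainable accuracy; for
  short chains (L ≈ 30, d₀ ≈ 1.3 Å) even perfect bound satisfaction
  leaves TM ≈ 0.9, so scores there sit near the information limit.
* The global-mirror chirality fix cannot repair a fold whose
  handedness is wrong in one segment only.
* Cβ-based distance maps, multi-chain complexes, sequence-independent
  (alignment-based) scoring and all-atom reconstruction are out of
  scope.
* Fixed-step steepest descent is deliberately simple (no momentum or
  quasi-Newton acceleration); deep convergence is obtained by the
  cascade structure rather than per-stage sophistication.
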