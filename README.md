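# dgfold

Distance-geometry folding of Cα protein traces.

`dgfold` folds a one-point-per-residue protein chain so that it
maximally satisfies a matrix of inter-residue distance restraints —
the computational core of distance-based protein structure
prediction.  Given CASP-RR-style restraints (residue pairs with
lower/upper distance bounds and a confidence) and a 3-state secondary
structure string, it optimizes a Cα trace with a cascade of
angular-space simulated annealing and Cartesian gradient descent,
resolves the mirror-image ambiguity inherent to distance data with a
secondary-structure chirality heuristic, and evaluates models with
TM-score and RMSD.  It is aimed at structural bioinformaticians who
want a small, headless, fully scriptable engine for studying how
distance-matrix quality (exact, bounded, noisy or predicted maps)
translates into 3D model quality.

## The model

A chain of L residues is reduced to its Cα positions
x₁…x_L (equivalently pseudo bond lengths ≈ 3.8 Å, planar angles θᵢ and
dihedral angles τᵢ).  A restraint set R = {(i, j, lᵢⱼ, uᵢⱼ, pᵢⱼ)}
defines the flat-bottom objective

    E(x) = Σ_(i,j)∈R  w_ij · v_ij²,     v_ij = max(0, l_ij − d_ij) + max(0, d_ij − u_ij)

with d_ij = ‖xᵢ − xⱼ‖ and w_ij = 1 (or the restraint confidence).  A
harmonic term k_b (d_{i,i+1} − 3.8)² maintains chain connectivity
during Cartesian optimization.  The optimizers additionally include a
weak centering term ε·(d_ij − (l_ij+u_ij)/2)², ε = 0.05, that selects
the central solution of the feasible region (see
`docs/methods.md`).  Because E is invariant under reflection, the
handedness of the result is fixed afterwards by comparing, over all
tetrapeptides lying inside helix/strand segments, the Cα
pseudo-dihedral against its ideal value (+50° for α-helix, −170° for
β-strand) for the model and its mirror image.

Model quality is measured with the template-modeling score

    TM = max over superpositions of (1/L) Σᵢ 1 / (1 + (dᵢ/d₀)²),
    d₀ = 1.24·(L−15)^⅓ − 1.8,

where TM > 0.5 conventionally indicates the correct fold.

## Worked example

```python
from dgfold import fixtures, perturb
from dgfold.model import CaFoldingModel

# a synthetic compact 68-residue alpha/beta target with known SS
native, ss = fixtures.make_alpha_beta_target()

# restraints: floor/ceil of the true distances (bounds within 1 Å)
rs = perturb.near_native_restraints(native)

model = CaFoldingModel(rs, secondary_structure=ss)
result = model.fit("case-study", seed=0)   # 1x annealing + 3x descent
print(result.summary())
print(f"TM-score vs native: {result.score(native).tm_score:.3f}")
```

prints

```
Distance-restraint folding results
==========================================
chain length          68
restraints            2278
cascade stages        sa + gd + gd + gd
initial objective     256330
final objective       0.130495
restraint energy      0.0277414
connectivity energy   0.0139522
satisfied restraints  2216/2278
chirality             mirrored (cost 2174.9 vs mirror 37.7, 29 windows)
TM-score vs native: 0.999
```

i.e. the cascade drives the objective from ~2.6·10⁵ down to ~0.1 (the
62 still-violated restraints overshoot their bounds by ~0.02 Å in
total), the optimizer happened to land in the left-handed mirror fold
— which distance data cannot distinguish — and the chirality check
flipped it back, leaving a trace that matches the generating
structure almost exactly (TM ≈ 1, where ≥ 0.5 is the same fold and
≥ 0.9 is near-atomic agreement at this length).

The same pipeline is available from the shell:

```sh
dgfold fixture --target -o target          # target.pdb + target.ss
dgfold mkrr target.pdb -o target.rr --sigma 1 --level 0.5 --seed 7
dgfold fold target.rr --ss target.ss -o model.pdb --seed 0
dgfold score model.pdb target.pdb
```

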