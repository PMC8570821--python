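# Methods

## Model and procedure

`enmsampler` generates conformational ensembles by alternating three
operations over generations.

**Elastic-network deformation.** Every residue contributes one network
node: its Cα atom, or for nucleotides the P atom (C4' as fallback).
Nodes within a cutoff `r_c` are connected by identical harmonic springs of
stiffness γ; the resulting 3n×3n Hessian has off-diagonal superelements
−(γ/r²)·ddᵀ and row-sum-zero diagonal blocks.  The model assumes the
input geometry is the energy minimum, so the spectrum carries exactly six
zero modes (rigid translations/rotations); any other count means the
network is degenerate (collinear or underconnected) and the run aborts
rather than sampling corrupted directions.  The `m` softest nonrigid
eigenvectors are extended to all atoms by the rigid-residue rule — every
atom copies its node's 3-vector — and a child conformer is the parent plus
a uniform-random linear combination of these modes, rescaled so its
unsuperposed Cα RMSD from the parent is exactly `target_rmsd`.  The
rescaling makes the coefficient distribution irrelevant to the step size:
only the direction in mode space is random, which keeps runs exactly
reproducible and parameter-light.  Mode displacements contain no
rigid-body component, so no superposition is needed before measuring the
step.

**RMSD clustering.** A generation's conformers (all parents pooled, so the
representative count stays bounded) are compared by minimum Cα RMSD after
optimal rigid superposition (Kabsch, proper rotations only).  The full
matrix is computed from per-pair 3×3 cross-covariances via
rmsd² = (G_i + G_j − 2Σσ)/n with sign-corrected singular values; because
that form cancels catastrophically for near-identical pairs, entries below
10⁻⁴ Å are recomputed from the explicit superposition residual.
Agglomerative clustering (average linkage by default; complete and Ward
available) is cut either into exactly `min(maxclust, M)` clusters — the
default, which fixes the per-generation output size — or at an RMSD
threshold.  Each cluster is represented by its medoid (summed-distance
minimizer; ties to the lowest conformer index).

**Relaxation.** Deformation along extended modes distorts local geometry
(the rigid-residue extension stretches bonds at hinge points), so
representatives are relaxed before seeding the next generation.  The
built-in backend minimizes a purely geometric restraint energy: harmonic
terms on a fixed bond list (heavy-atom pairs within `bond_detect_max` =
1.9 Å in the input, plus consecutive Cα pairs for coarse-grained
structures, equilibrium = input distance) plus a soft-sphere repulsion
k_rep(d₀−r)² between nonbonded heavy pairs closer than d₀ = 2.5 Å.
Hydrogens are carried through but excluded from repulsion.  Minimization
is steepest descent with backtracking: the step direction is the force
field normalized to a maximum per-atom displacement of `step_size`, any
energy increase halves the step, and an increase is never accepted — so
the energy trace is non-increasing by construction, an invariant the tests
assert directly.  Physics-grade relaxation (force-field MD in implicit or
explicit solvent) is deliberately an *external adapter*: any callable
mapping (coords, structure, config) → (coords, energy) with unchanged atom
ordering plugs into the same pipeline slot, keeping the core free of MD
dependencies.  A mock adapter ships for contract tests.

**Iteration.** The input is relaxed once before sampling (deform from a
local minimum).  Modes are recomputed for each parent every generation by
default — the method's point is that each fed-back conformer is deformed
along *its own* current soft modes — with a config flag to reuse the
input's modes.  Relaxed representative coordinates are what feeds back.
Random streams derive from (master_seed, generation, parent), so results
are independent of parent processing order and bit-reproducible; the run
record checkpoints after every generation, and `resume` continues an
interrupted run to a result identical to an uninterrupted one, refusing a
changed configuration with a field diff.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `cutoff` | 15 Å | ANM spring cutoff; common practice for Cα networks |
| `gamma` | 1 | uniform spring constant (only ratios matter) |
| `n_modes` | 3 | softest nonrigid modes used for deformation |
| `target_rmsd` | 1.0 Å | exact Cα RMSD of each deformation step |
| `n_confs` | 50 | children per parent per generation |
| `maxclust` | 60 | clusters (= representatives) per generation |
| `linkage` | average | agglomeration rule for RMSD clustering |
| `n_gens` | 5 | generations |
| `k_bond`, `k_rep` | 100, 10 | restraint stiffnesses (arbitrary energy/Å²) |
| `rep_cutoff` | 2.5 Å | heavy-atom soft-sphere diameter |
| `step_size`, `max_steps`, `force_tol` | 0.01 Å, 500, 10⁻³ | minimizer controls |

With the defaults, five generations at 60 representatives each emit 300
conformers whenever each generation pools at least 60 candidates.

## Synthetic toys

The fixture generator builds two deterministic Cα+CB polymers: an ideal
α-helical trace (rise 1.5 Å, radius 2.3 Å, 100° twist; one pseudo
side-chain atom offset 1.5 Å radially per residue) and a two-domain
construct — two such helices joined by an extended linker.  The linker
hugs its axis with a small (0.7 Å) lateral spiral: an exactly collinear
segment would give the elastic network zero-energy mechanisms and spurious
rigid-body modes.  These toys exercise every stage — node selection,
all-atom extension (CB follows its CA), virtual-backbone bonding, hinge
motion — without any chemistry.  They do *not* emulate real side-chain
packing, sequence heterogeneity, secondary-structure diversity or
solvation, so passing tests demonstrate the algorithm's correctness and
invariants, not force-field-level realism of sampled conformers on real
proteins.

The two-domain toy's softest nonrigid mode is the counter-rotation of the
domains about the axis joining them — the hinge-type collective motion the
method is designed to amplify — which the tests verify against an
analytically constructed rotation field.

## Numerical choices

- Eigenproblems use full dense symmetric decomposition; systems of
  interest here are desk-scale (hundreds to thousands of nodes).
- Zero modes are classified by a relative threshold (10⁻⁸ × largest
  eigenvalue); exactly six must fall below it.
- Superposition enforces proper rotations (det +1) and rejects collinear
  selections, where the fit is ill-posed.  Coincident or collinear node
  sets are rejected when building the network; planar sets are legal for
  three nodes (their out-of-plane freedoms are rigid motions) and are
  caught by the six-zero-mode check otherwise.
- PCA superposes conformers iteratively onto the running mean until the
  mean shifts < 10⁻⁶ Å (RMS), then performs a final alignment pass against
  the converged mean so projections reproduce the training deviations
  exactly; variances use the (M−1) normalization; component signs follow
  the largest-entry-positive convention.
- KDE bandwidth follows Scott's rule by default.  Scott's factor depends
  on the sample size, so an explicit kernel-covariance override is
  available when estimates must be comparable across ensembles of
  different size; the evaluation grid pads the data range by 4 kernel
  standard deviations so the map integrates to 1 within 10⁻³.
- Cluster-count cuts use the dendrogram's merge sequence (`cut_tree`),
  which yields exactly `min(maxclust, M)` clusters even under tied merge
  heights; labels are renumbered by first appearance for determinism.
- Medoid ties break toward the lowest conformer index.
- All-zero mode-coefficient draws are redrawn (bounded retries); a zero
  deformation target short-circuits to exact copies of the parent.

## Scope of the test problems

Tests and the acceptance script run on the synthetic toys at small scale:
the full-pipeline checks use a 12-residue helix for the 5-generation ×
60-representative run (300 conformers) and a 40-residue two-domain toy for
excursion-growth and determinism checks, with 3600-conformer generation
pools as the largest clustering inputs.  The 16-residue two-domain toy is
deliberately *not* used for long runs: repeated ångström-scale deformation
of so small a network can disconnect it, which the pipeline correctly
reports as a degeneracy error rather than sampling through it.

## Known limitations

- The built-in relaxer restores bond lengths and removes clashes; it knows
  nothing about torsions, chirality or electrostatics.  For
  publication-grade conformers, register an MD adapter.
- Hydrogens and missing heavy atoms are not added; inputs are taken as
  given (waters are dropped, altloc B+ skipped, first model only).
- The inter-domain angle tool needs user-supplied residue selections for
  the three groups; no protein-specific definitions are built in.
- Selections implement a deliberately small grammar (`calpha`, `chain`,
  `resid`, `name`, `and`).
- `maxclust` mode bounds ensemble growth; threshold mode can multiply
  representatives without bound on diffuse ensembles.
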