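# enmsampler

Iterative elastic-network-mode sampling of biomolecular conformational
space, with RMSD clustering, structural relaxation and ensemble-analysis
tools.

Unbiased sampling of large conformational changes is expensive with plain
molecular dynamics: collective transitions (domain opening, hinge bending)
sit behind barriers that nanosecond trajectories rarely cross.
`enmsampler` is for structural biologists and modellers who need broad
conformer ensembles cheaply — for docking, for mapping accessible states,
or for seeding further simulation — starting from a single PDB structure.

## The method

The pipeline repeats three steps for `g = 1 … n_gens` generations:

1. **Deform.** The parent structure's Cα atoms define an anisotropic
   network model (ANM): identical springs of stiffness γ connect node pairs
   within a cutoff `r_c` (default 15 Å).  The Hessian superelement for
   connected nodes *i* ≠ *j* is

       H_ij = −(γ / r_ij²) · d_ij d_ijᵀ,

   with d_ij the coordinate difference.  Its six zero modes are rigid-body
   motions; the `m` softest nonrigid eigenvectors are the *global modes*.
   Each child conformer is displaced along a random linear combination
   Σ_k c_k v_k (c_k ~ U(−1, 1)), rescaled so that the unsuperposed Cα RMSD
   from the parent equals `target_rmsd` exactly.
2. **Cluster.** The generation's pooled conformers are clustered
   hierarchically on pairwise Kabsch-superposed Cα RMSD and each cluster's
   medoid becomes a representative (default: 60 clusters per generation).
3. **Relax.** Representatives are structurally relaxed — by the built-in
   geometric minimizer (harmonic bond restraints + soft-sphere repulsion,
   monotone steepest descent), or by any external engine registered through
   the adapter contract — and fed back as the next generation's parents.

Because each generation deforms, filters and re-minimizes, the ensemble
makes progressively larger excursions from the starting minimum while
staying locally plausible.  Analysis tools map the result: essential-
dynamics PCA of superposed Cα coordinates, projections onto the leading
components, Gaussian-KDE population landscapes, and inter-domain angle
reaction coordinates.

## A worked example

```python
import enmsampler as es
from enmsampler import pipeline as pl

structure = es.make_toy(es.ToySpec(n_residues=40, geometry="two_domain",
                                   linker_length=4))
config = pl.config_from_dict({"n_gens": 3, "n_confs": 10, "maxclust": 4,
                              "target_rmsd": 1.0, "seed": 7})
ensemble, record = pl.run(structure, config)
for gen in record.generations:
    print(gen["generation"], gen["parents"], gen["conformers"],
          gen["representatives"])
```

prints

```
1 1 10 4
2 4 40 4
3 4 40 4
```

— generation 1 deforms the single input into 10 conformers and keeps 4
cluster medoids; each later generation deforms its 4 parents into 40
pooled conformers and keeps 4, so the final ensemble holds
3 × 4 = 12 relaxed conformers with full lineage.  With the default
configuration (5 generations, 60 clusters, pooled conformer counts of at
least 60) a run emits 300 conformers.

The same pipeline is available from the shell:

```bash
enmsampler run --pdb input.pdb --n-gens 5 --n-confs 60 --maxclust 60 \
    --rmsd 1.0 --seed 1 --out run_dir --formats pdb,dcd
```

Outputs are a multi-model PDB and/or CHARMM-style DCD plus a JSON run
record; interrupted runs continue with `enmsampler resume --out run_dir`.
The `examples/` directory walks through each capability.

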