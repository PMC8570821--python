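"""Cluster an ensemble by pairwise Cα RMSD and relax the representatives."""

import numpy as np

import enmsampler as es

helix = es.make_toy(es.ToySpec(n_residues=12, geometry="helix"))
ca = es.select(helix, "calpha")
modes = es.compute_anm_modes(helix)
ensemble = es.generate_conformers(
    helix.coords, modes, ca, es.SamplingParams(n_confs=20, target_rmsd=1.5, seed=3)
)

dist = es.pairwise_rmsd(ensemble, ca)
result = es.representatives(dist, es.cluster(dist, es.ClusterParams(maxclust=4)))
print("cluster sizes:", result.sizes.tolist())
print("medoid conformers:", result.representatives.tolist())
# The medoid minimizes the summed RMSD to its cluster mates: the most
# central conformer stands in for the whole cluster.

bonds = es.build_bond_list(helix)
for r in result.representatives:
    relaxed = es.relax(ensemble.coords[r], bonds, heavy_mask=~helix.hydrogen_mask())
    print(
        f"conformer {r}: energy {relaxed.energy_trace[0]:.2f} -> "
        f"{relaxed.energy_trace[-1]:.2e} in {relaxed.steps_taken} steps "
        f"(converged={relaxed.converged})"
    )
# Relaxation restores bond lengths distorted by the rigid-residue mode
# extension and removes steric clashes before the next generation starts.
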