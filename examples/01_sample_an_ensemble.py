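"""Run the full iterative sampling pipeline on a toy structure.

Builds a small two-domain polymer, runs three generations of
mode-deform / cluster / relax, and prints what came out.
"""

import enmsampler as es
from enmsampler import pipeline as pl

structure = es.make_toy(es.ToySpec(n_residues=40, geometry="two_domain", linker_length=4))

config = pl.config_from_dict({
    "n_gens": 3,        # sample -> cluster -> relax cycles
    "n_confs": 10,      # children per parent per generation
    "maxclust": 4,      # representatives kept per generation
    "target_rmsd": 1.0, # Cα RMSD of each deformation step, Å
    "seed": 7,
    "output_dir": "scratch_run",
    "output_formats": "pdb,dcd",
})

ensemble, record = pl.run(structure, config)

print(f"input atoms:        {structure.n_atoms}")
print(f"output conformers:  {ensemble.n_conformers}")
for gen in record.generations:
    print(
        f"  generation {gen['generation']}: {gen['parents']} parents -> "
        f"{gen['conformers']} conformers -> {gen['representatives']} representatives"
    )
print("ensemble written to scratch_run/ensemble.pdb and .dcd")
# Each generation pools parents x n_confs deformed conformers and keeps one
# medoid per RMSD cluster, so the ensemble grows by maxclust per generation.
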