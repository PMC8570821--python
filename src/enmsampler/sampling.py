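"""Mode-space conformer generation.

Each child conformer is the parent displaced along a random linear
combination of the global modes.  Coefficients are drawn uniformly on
[-1, 1] per mode; the combined displacement is then rescaled so that the
unsuperposed Cα RMSD between child and parent equals ``target_rmsd``
exactly — the random draw fixes only the *direction* in mode space, the
rescaling fixes the step size.  No superposition is needed because mode
displacements contain no rigid-body component by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .anm import ModeBasis
from .ensemble import Ensemble
from .errors import ContractError, SamplingError

_MAX_REDRAWS = 100


@dataclass
class SamplingParams:
    """Conformer-generation tunables.

    n_confs
        Children generated per parent per generation.
    target_rmsd
        Deformation magnitude: the unsuperposed Cα RMSD (Å) of every child
        from its parent.
    seed
        Master seed for standalone use; the pipeline derives per-parent
        streams from its own master seed instead.
    """

    n_confs: int = 50
    target_rmsd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_confs < 1:
            raise ContractError("n_confs must be >= 1")
        if self.target_rmsd < 0:
            raise ContractError("target_rmsd must be >= 0")


def child_rng(master_seed: int, generation: int, parent_index: int) -> np.random.Generator:
    """Deterministic per-(generation, parent) random stream.

    Seeding by the (master_seed, generation, parent) triple makes the
    conformers of each parent independent of the order in which parents are
    processed, so results are reproducible under any parallelization.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed), int(generation), int(parent_index)])
    )


def generate_conformers(
    parent_coords: np.ndarray,
    modes: ModeBasis,
    calpha_mask: np.ndarray,
    params: SamplingParams,
    rng: np.random.Generator | None = None,
    generation: int = 1,
    parent_index: int = 0,
) -> Ensemble:
    """Generate ``params.n_confs`` children of one parent conformer.

    Each child c is ``parent + alpha * sum_k c_k v_k`` with c_k ~ U(-1, 1)
    and alpha chosen so the child's unsuperposed Cα RMSD from the parent is
    exactly ``target_rmsd``.  All-zero coefficient draws are redrawn.
    """
    params.validate()
    if modes.atom_vectors is None:
        raise ContractError("modes must be extended to all atoms before sampling")
    parent_coords = np.asarray(parent_coords, dtype=float)
    n_atoms = parent_coords.shape[0]
    if parent_coords.shape != (n_atoms, 3):
        raise ContractError("parent_coords must be (N, 3)")
    if modes.atom_vectors.shape[1] != 3 * n_atoms:
        raise ContractError("mode vectors do not match the parent atom count")
    calpha_mask = np.asarray(calpha_mask, dtype=bool)
    n_ca = int(calpha_mask.sum())
    if n_ca == 0:
        raise ContractError("calpha_mask selects no atoms")
    if rng is None:
        rng = np.random.default_rng(params.seed)

    m = modes.n_modes
    children = np.empty((params.n_confs, n_atoms, 3))
    for c in range(params.n_confs):
        for _ in range(_MAX_REDRAWS):
            coeffs = rng.uniform(-1.0, 1.0, size=m)
            disp = (coeffs @ modes.atom_vectors).reshape(n_atoms, 3)
            ca_norm = float(np.linalg.norm(disp[calpha_mask]))
            if ca_norm > 0.0:
                break
        else:
            raise SamplingError(
                f"zero-norm Cα displacement after {_MAX_REDRAWS} redraws"
            )
        alpha = params.target_rmsd * np.sqrt(n_ca) / ca_norm
        children[c] = parent_coords + alpha * disp

    return Ensemble(
        coords=children,
        generation=np.full(params.n_confs, generation, dtype=int),
        parent=np.full(params.n_confs, parent_index, dtype=int),
    )
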