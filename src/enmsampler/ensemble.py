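"""Ordered multi-conformer container shared by sampling, clustering and I/O."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError


@dataclass
class Ensemble:
    """An ordered set of conformers over one fixed topology.

    Parameters
    ----------
    coords
        ``(M, N, 3)`` coordinates in Å.
    generation
        Per-conformer generation index; generation 0 is the input structure,
        generation g the batch produced by the g-th sample/cluster/relax cycle.
    parent
        Per-conformer index into the *previous* generation's representatives;
        ``-1`` marks the input structure itself.
    """

    coords: np.ndarray
    generation: np.ndarray = field(default=None)  # type: ignore[assignment]
    parent: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ContractError(
                f"ensemble coords must be (M, N, 3), got {self.coords.shape}"
            )
        m = self.coords.shape[0]
        if self.generation is None:
            self.generation = np.zeros(m, dtype=int)
        if self.parent is None:
            self.parent = np.full(m, -1, dtype=int)
        self.generation = np.asarray(self.generation, dtype=int)
        self.parent = np.asarray(self.parent, dtype=int)
        if self.generation.shape != (m,) or self.parent.shape != (m,):
            raise ContractError("generation/parent labels must have length M")
        if m > 1 and np.any(np.diff(self.generation) < 0):
            raise ContractError("generation labels must be non-decreasing")

    @property
    def n_conformers(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def __len__(self) -> int:  # pragma: no cover - trivial
        return self.n_conformers


def concatenate(parts: list[Ensemble]) -> Ensemble:
    """Concatenate ensembles over the same topology, preserving order."""
    if not parts:
        raise ContractError("cannot concatenate zero ensembles")
    n = parts[0].n_atoms
    for p in parts:
        if p.n_atoms != n:
            raise ContractError("all ensembles must share the atom count")
    return Ensemble(
        coords=np.concatenate([p.coords for p in parts], axis=0),
        generation=np.concatenate([p.generation for p in parts]),
        parent=np.concatenate([p.parent for p in parts]),
    )
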