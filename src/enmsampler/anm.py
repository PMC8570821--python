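"""Anisotropic network model (ANM) normal modes.

The ANM places identical harmonic springs between node pairs (Cα atoms, or
the P/C4' atom for nucleotides) within a distance cutoff.  The 3n×3n Hessian
has, for connected nodes i≠j, the off-diagonal 3×3 superelement

    H_ij = -(gamma / r_ij^2) * d_ij d_ij^T

with d_ij the coordinate difference vector, and diagonal superelements equal
to minus the sum of the row's off-diagonal superelements.  Its six
zero-eigenvalue modes are rigid translations/rotations; the softest nonrigid
eigenvectors are the global modes used for conformer deformation, extended
to all atoms by the rigid-residue rule (every atom copies its node's
displacement).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from scipy.spatial import cKDTree

from .errors import ContractError, DegeneracyError, ModelError
from .structure_io import Structure

#: atom names that may serve as the per-residue network node, in priority order
NODE_ATOM_PRIORITY = ("CA", "P", "C4'")


@dataclass
class AnmParams:
    """ANM tunables.

    cutoff
        Spring cutoff in Å.  15 Å is common practice for Cα networks.
    gamma
        Uniform spring constant (arbitrary units; only ratios matter).
    n_modes
        Number of softest nonrigid modes to retain.
    zero_mode_tol
        Eigenvalues below ``zero_mode_tol * max(eigenvalue)`` count as
        rigid-body modes; exactly six must fall below it.
    """

    cutoff: float = 15.0
    gamma: float = 1.0
    n_modes: int = 3
    zero_mode_tol: float = 1e-8

    def validate(self) -> None:
        if self.cutoff <= 0 or self.gamma <= 0:
            raise ContractError("cutoff and gamma must be positive")
        if self.n_modes < 1:
            raise ContractError("n_modes must be >= 1")


@dataclass
class ModeBasis:
    """Orthonormal nonrigid ANM modes on nodes, optionally extended to atoms."""

    node_mask: np.ndarray           # boolean over atoms; True at network nodes
    eigenvalues: np.ndarray         # (m,) ascending, strictly positive
    node_vectors: np.ndarray        # (m, 3n) orthonormal rows
    atom_vectors: np.ndarray | None = None  # (m, 3N) after extension

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)


def _check_not_collinear(coords: np.ndarray) -> None:
    centered = coords - coords.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[0] == 0 or s[1] / s[0] < 1e-10:
        raise ModelError("node coordinates are (near-)collinear or coincident; "
                         "the network would have extra zero modes")


def build_hessian(coords: np.ndarray, params: AnmParams | None = None) -> np.ndarray:
    """Assemble the 3n×3n ANM Hessian for node coordinates (n, 3) in Å."""
    params = params or AnmParams()
    params.validate()
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ContractError("node coords must be an (n, 3) matrix")
    if n < 3:
        raise ContractError(f"ANM needs at least 3 nodes, got {n}")
    _check_not_collinear(coords)

    pairs = sorted(cKDTree(coords).query_pairs(params.cutoff))
    degree = np.zeros(n, dtype=int)
    hessian = np.zeros((3 * n, 3 * n))
    for i, j in pairs:
        d = coords[j] - coords[i]
        r2 = float(d @ d)
        if r2 == 0.0:
            raise ModelError(f"nodes {i} and {j} coincide")
        block = -(params.gamma / r2) * np.outer(d, d)
        hessian[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] = block
        hessian[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] = block
        hessian[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] -= block
        hessian[3 * j : 3 * j + 3, 3 * j : 3 * j + 3] -= block
        degree[i] += 1
        degree[j] += 1

    isolated = np.nonzero(degree == 0)[0]
    if isolated.size:
        raise ModelError(
            f"node(s) {isolated.tolist()} have no neighbor within "
            f"{params.cutoff} Å; the network is disconnected"
        )
    return hessian


def compute_modes(
    hessian: np.ndarray,
    params: AnmParams | None = None,
    node_mask: np.ndarray | None = None,
) -> ModeBasis:
    """Diagonalize the Hessian and return the softest nonrigid modes.

    Exactly six eigenvalues must classify as rigid-body (below
    ``zero_mode_tol`` relative to the largest); otherwise the network is
    degenerate and a :class:`DegeneracyError` is raised.
    """
    params = params or AnmParams()
    params.validate()
    hessian = np.asarray(hessian, dtype=float)
    w, v = eigh(hessian)
    w_max = w[-1]
    if w_max <= 0:
        raise DegeneracyError("Hessian has no positive eigenvalues")
    n_zero = int(np.sum(w < params.zero_mode_tol * w_max))
    if n_zero != 6:
        raise DegeneracyError(
            f"expected exactly 6 rigid-body modes, found {n_zero}: the network "
            "is collinear, disconnected, or the tolerance is unsuitable"
        )
    available = len(w) - 6
    if params.n_modes > available:
        raise ContractError(
            f"n_modes={params.n_modes} exceeds the {available} available "
            "nonrigid modes"
        )
    sel = slice(6, 6 + params.n_modes)
    eigenvalues = w[sel].copy()
    node_vectors = v[:, sel].T.copy()
    if node_mask is None:
        node_mask = np.ones(len(w) // 3, dtype=bool)
    return ModeBasis(
        node_mask=np.asarray(node_mask, dtype=bool),
        eigenvalues=eigenvalues,
        node_vectors=node_vectors,
    )


def node_mask_for(structure: Structure) -> np.ndarray:
    """Boolean mask of network nodes: one Cα (or P / C4') per residue."""
    keys = structure.residue_keys()
    chosen: dict[tuple, int] = {}
    rank = {name: k for k, name in enumerate(NODE_ATOM_PRIORITY)}
    for i, key in enumerate(keys):
        name = str(structure.atom_name[i])
        if name not in rank:
            continue
        if key not in chosen or rank[name] < rank[str(structure.atom_name[chosen[key]])]:
            chosen[key] = i
    missing = [key for key in dict.fromkeys(keys) if key not in chosen]
    if missing:
        raise ModelError(
            f"residue(s) {missing[:5]} have no node atom "
            f"(one of {NODE_ATOM_PRIORITY}); cannot build the network"
        )
    mask = np.zeros(structure.n_atoms, dtype=bool)
    mask[list(chosen.values())] = True
    return mask


def extend_to_all_atoms(basis: ModeBasis, structure: Structure) -> ModeBasis:
    """Fill in the all-atom mode vectors by the rigid-residue rule.

    Each atom inherits the 3-vector of its residue's node for every mode;
    node atoms keep their own rows unchanged.
    """
    mask = np.asarray(basis.node_mask, dtype=bool)
    if mask.sum() * 3 != basis.node_vectors.shape[1]:
        raise ContractError("node_mask size inconsistent with node_vectors")
    keys = structure.residue_keys()
    node_indices = np.nonzero(mask)[0]
    node_of_residue = {keys[i]: rank for rank, i in enumerate(node_indices)}
    atom_to_node = np.empty(structure.n_atoms, dtype=int)
    for i, key in enumerate(keys):
        if key not in node_of_residue:
            raise ModelError(f"residue {key} has no network node to extend from")
        atom_to_node[i] = node_of_residue[key]

    m = basis.n_modes
    node_vec = basis.node_vectors.reshape(m, -1, 3)
    atom_vectors = node_vec[:, atom_to_node, :].reshape(m, 3 * structure.n_atoms)
    return ModeBasis(
        node_mask=mask,
        eigenvalues=basis.eigenvalues.copy(),
        node_vectors=basis.node_vectors.copy(),
        atom_vectors=atom_vectors,
    )


def compute_anm_modes(
    structure: Structure,
    params: AnmParams | None = None,
    coords: np.ndarray | None = None,
) -> ModeBasis:
    """Convenience: node selection → Hessian → modes → all-atom extension.

    ``coords`` overrides the structure's coordinates (same topology), which
    the pipeline uses when recomputing modes for each new parent conformer.
    """
    params = params or AnmParams()
    mask = node_mask_for(structure)
    all_coords = structure.coords if coords is None else np.asarray(coords, float)
    if all_coords.shape != (structure.n_atoms, 3):
        raise ContractError("override coords must match the structure atom count")
    hessian = build_hessian(all_coords[mask], params)
    basis = compute_modes(hessian, params, node_mask=mask)
    working = structure if coords is None else structure.with_coords(all_coords)
    return extend_to_all_atoms(basis, working)
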