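"""Structural relaxation of representative conformers.

The pipeline's relaxation stage has one job: return mode-deformed conformers
to locally plausible geometry before they seed the next generation.  The
built-in backend is a dependency-free geometric minimizer over a harmonic
bond-restraint term plus a soft-sphere repulsion between heavy atoms:

    E = sum_bonds k_bond (|r_i - r_j| - b_ij)^2
      + sum_{nonbonded heavy pairs with |r_i - r_j| < d0} k_rep (d0 - |r_i - r_j|)^2

minimized by steepest descent with backtracking (step halved on any energy
increase, increases never accepted), which makes the energy trace monotone
by construction.  Physics-grade relaxation (force-field MD) plugs in through
the external-adapter contract instead; the pipeline treats both identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConfigurationError, ContractError, NumericError, RelaxationError
from .structure_io import Structure


@dataclass
class RelaxParams:
    """Built-in minimizer tunables (energies in arbitrary units, lengths Å)."""

    backend: str = "builtin"
    k_bond: float = 100.0      # bond restraint stiffness, energy/Å²
    k_rep: float = 10.0        # soft-sphere repulsion stiffness, energy/Å²
    rep_cutoff: float = 2.5    # d0: nonbonded pairs closer than this repel
    bond_detect_max: float = 1.9   # heavy-atom pairs within this (Å) are bonds
    step_size: float = 0.01    # Å displacement per unit normalized force
    max_steps: int = 500
    force_tol: float = 1e-3    # max per-atom force magnitude at convergence

    def validate(self) -> None:
        values = (
            self.k_bond, self.k_rep, self.rep_cutoff, self.bond_detect_max,
            self.step_size, self.max_steps, self.force_tol,
        )
        if any(v <= 0 for v in values):
            raise ContractError("all relaxation parameters must be positive")
        if self.backend not in ("builtin", "external"):
            raise ContractError("backend must be 'builtin' or 'external'")


@dataclass
class RelaxResult:
    coords: np.ndarray
    energy_trace: list = field(default_factory=list)
    converged: bool = False
    steps_taken: int = 0


def build_bond_list(
    structure: Structure, params: RelaxParams | None = None
) -> list[tuple[int, int, float]]:
    """Detect the fixed bond list from the reference structure.

    Heavy-atom pairs within ``bond_detect_max`` Å in the reference geometry
    are bonded with equilibrium length equal to their reference distance.
    Coarse-grained structures additionally bond consecutive Cα atoms of each
    chain (the virtual backbone).  The list is built once per run and reused
    for every conformer.
    """
    params = params or RelaxParams()
    params.validate()
    heavy = ~structure.hydrogen_mask()
    heavy_idx = np.nonzero(heavy)[0]
    coords = structure.coords
    bonds: dict[tuple[int, int], float] = {}
    if len(heavy_idx) >= 2:
        tree = cKDTree(coords[heavy_idx])
        for a, b in tree.query_pairs(params.bond_detect_max):
            i, j = int(heavy_idx[a]), int(heavy_idx[b])
            key = (min(i, j), max(i, j))
            bonds[key] = float(np.linalg.norm(coords[i] - coords[j]))
    if structure.coarse_grained:
        ca = [
            i for i in range(structure.n_atoms)
            if str(structure.atom_name[i]) == "CA"
        ]
        for a, b in zip(ca[:-1], ca[1:]):
            if structure.chain_id[a] != structure.chain_id[b]:
                continue
            key = (min(a, b), max(a, b))
            bonds[key] = float(np.linalg.norm(coords[a] - coords[b]))
    return sorted((i, j, b) for (i, j), b in bonds.items())


def _energy_forces(
    coords: np.ndarray,
    bond_i: np.ndarray,
    bond_j: np.ndarray,
    bond_b: np.ndarray,
    bonded_keys: set,
    heavy_idx: np.ndarray,
    params: RelaxParams,
) -> tuple[float, np.ndarray]:
    energy = 0.0
    forces = np.zeros_like(coords)

    if len(bond_i):
        d = coords[bond_i] - coords[bond_j]
        r = np.linalg.norm(d, axis=1)
        dev = r - bond_b
        energy += float(params.k_bond * np.sum(dev**2))
        # dE/dr = 2 k (r - b); force along the pair axis
        coef = (2.0 * params.k_bond * dev / np.maximum(r, 1e-12))[:, None]
        np.subtract.at(forces, bond_i, coef * d)
        np.subtract.at(forces, bond_j, -coef * d)

    if len(heavy_idx) >= 2:
        tree = cKDTree(coords[heavy_idx])
        for a, b in tree.query_pairs(params.rep_cutoff):
            i, j = int(heavy_idx[a]), int(heavy_idx[b])
            if (min(i, j), max(i, j)) in bonded_keys:
                continue
            d = coords[i] - coords[j]
            r = float(np.linalg.norm(d))
            if r >= params.rep_cutoff or r < 1e-12:
                continue
            gap = params.rep_cutoff - r
            energy += params.k_rep * gap**2
            coef = 2.0 * params.k_rep * gap / r   # -dE/dr / r, pushes apart
            forces[i] += coef * d
            forces[j] -= coef * d

    if not np.isfinite(energy) or not np.all(np.isfinite(forces)):
        raise NumericError("non-finite energy or force during relaxation")
    return energy, forces


def relax(
    conformer_coords: np.ndarray,
    bonds: list[tuple[int, int, float]],
    params: RelaxParams | None = None,
    heavy_mask: np.ndarray | None = None,
) -> RelaxResult:
    """Minimize the restraint energy of one conformer.

    Steepest descent: the step direction is the force field normalized so
    the largest per-atom displacement is ``step_size``; on an energy
    increase the step is halved (backtracking) and an increase is never
    accepted, so ``energy_trace`` is non-increasing.  Convergence is
    declared when the maximum per-atom force drops below ``force_tol``.
    """
    params = params or RelaxParams()
    params.validate()
    coords = np.array(conformer_coords, dtype=float)
    n = coords.shape[0]
    if coords.shape != (n, 3):
        raise ContractError("conformer coords must be (N, 3)")
    if heavy_mask is None:
        heavy_mask = np.ones(n, dtype=bool)
    heavy_idx = np.nonzero(np.asarray(heavy_mask, dtype=bool))[0]

    bond_i = np.array([b[0] for b in bonds], dtype=int)
    bond_j = np.array([b[1] for b in bonds], dtype=int)
    bond_b = np.array([b[2] for b in bonds], dtype=float)
    bonded_keys = {(min(i, j), max(i, j)) for i, j, _ in bonds}

    try:
        energy, forces = _energy_forces(
            coords, bond_i, bond_j, bond_b, bonded_keys, heavy_idx, params
        )
    except NumericError as exc:
        raise NumericError(f"{exc} (iteration 0)") from None
    trace = [energy]
    converged = False
    for iteration in range(1, params.max_steps + 1):
        f_max = float(np.max(np.linalg.norm(forces, axis=1))) if n else 0.0
        if f_max < params.force_tol:
            converged = True
            break
        direction = forces / f_max
        step = params.step_size
        accepted = False
        for _ in range(40):
            trial = coords + step * direction
            try:
                e_trial, f_trial = _energy_forces(
                    trial, bond_i, bond_j, bond_b, bonded_keys, heavy_idx, params
                )
            except NumericError as exc:
                raise NumericError(f"{exc} (iteration {iteration})") from None
            if e_trial <= energy:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break  # stuck at numerical resolution; keep the best point
        coords, energy, forces = trial, e_trial, f_trial
        trace.append(energy)
    if not converged and n:
        f_max = float(np.max(np.linalg.norm(forces, axis=1)))
        converged = f_max < params.force_tol
    return RelaxResult(
        coords=coords,
        energy_trace=trace,
        converged=converged,
        steps_taken=len(trace) - 1,
    )


def relax_structure(
    structure: Structure,
    conformer_coords: np.ndarray,
    bonds: list[tuple[int, int, float]],
    params: RelaxParams | None = None,
) -> RelaxResult:
    """Relax with the structure's hydrogen atoms excluded from repulsion."""
    return relax(
        conformer_coords, bonds, params, heavy_mask=~structure.hydrogen_mask()
    )


# ---------------------------------------------------------------------------
# External backend contract

#: adapter signature: fn(coords (N,3), structure, config dict) -> (coords, energy)
AdapterFn = Callable[[np.ndarray, Structure, dict], tuple[np.ndarray, float]]

_ADAPTERS: dict[str, AdapterFn] = {}


def register_adapter(name: str, fn: AdapterFn) -> None:
    """Register an external relaxation backend under ``name``."""
    _ADAPTERS[name] = fn


def mock_adapter(coords: np.ndarray, structure: Structure, config: dict):
    """Reference adapter for tests: returns its input unchanged, energy 0."""
    return np.array(coords, dtype=float), 0.0


register_adapter("mock", mock_adapter)


def relax_external(
    conformer_coords: np.ndarray,
    structure: Structure,
    adapter_config: dict | None = None,
    context: str = "",
) -> RelaxResult:
    """Relax one conformer through a registered external adapter.

    The contract is minimal: same atom count and ordering in and out, finite
    energy.  Violations are surfaced as package errors with the pipeline's
    generation/conformer context attached.
    """
    adapter_config = dict(adapter_config or {})
    name = adapter_config.pop("adapter", None)
    if name is None or name not in _ADAPTERS:
        raise ConfigurationError(
            f"no external adapter registered under {name!r}; call "
            "enmsampler.relaxation.register_adapter(name, fn) with a callable "
            "(coords, structure, config) -> (coords, energy) and set "
            "adapter_config={'adapter': name, ...}"
        )
    coords = np.array(conformer_coords, dtype=float)
    try:
        out_coords, energy = _ADAPTERS[name](coords, structure, adapter_config)
    except Exception as exc:
        raise RelaxationError(
            f"external adapter {name!r} failed{' for ' + context if context else ''}: {exc}"
        ) from exc
    out_coords = np.asarray(out_coords, dtype=float)
    if out_coords.shape != coords.shape:
        raise ContractError(
            f"adapter {name!r} returned shape {out_coords.shape}, "
            f"expected {coords.shape}{' (' + context + ')' if context else ''}"
        )
    if not np.isfinite(energy):
        raise RelaxationError(f"adapter {name!r} returned non-finite energy")
    return RelaxResult(
        coords=out_coords, energy_trace=[float(energy)], converged=True, steps_taken=0
    )
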