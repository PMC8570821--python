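"""Deterministic synthetic toy structures.

Two geometries are provided: an ideal α-helical Cα trace and a two-domain
construct (two compact helices joined by an extended linker).  Each residue
carries its Cα plus one pseudo side-chain atom ("CB") offset radially, so the
all-atom mode-extension logic is exercised without any chemistry.  Toys are
flagged coarse-grained and are bit-reproducible for a fixed spec.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContractError
from .structure_io import Structure

HELIX_RISE = 1.5       # Å per residue along the axis
HELIX_RADIUS = 2.3     # Å, Cα distance from the axis
HELIX_TWIST = 100.0    # degrees per residue
CB_OFFSET = 1.5        # Å, radial pseudo side-chain offset
LINKER_SPACING = 3.8   # Å per residue in the extended linker


@dataclass
class ToySpec:
    """Recipe for one synthetic structure."""

    n_residues: int
    geometry: str = "helix"
    linker_length: int = 4
    seed: int = 0

    def validate(self) -> None:
        if self.n_residues < 4:
            raise ContractError("toy structures need n_residues >= 4")
        if self.geometry not in ("helix", "two_domain"):
            raise ContractError(
                f"geometry must be 'helix' or 'two_domain', got {self.geometry!r}"
            )
        if self.geometry == "two_domain":
            if self.linker_length < 1:
                raise ContractError("linker_length must be >= 1")
            if self.n_residues - self.linker_length < 8:
                raise ContractError(
                    "two_domain needs at least 4 residues per domain"
                )


def _helix_positions(n: int, z0: float = 0.0, phase: float = 0.0) -> tuple:
    """Cα and CB positions of an ideal helical segment starting at height z0."""
    i = np.arange(n)
    theta = np.deg2rad(HELIX_TWIST) * i + phase
    z = z0 + HELIX_RISE * i
    ca = np.stack([HELIX_RADIUS * np.cos(theta), HELIX_RADIUS * np.sin(theta), z], axis=1)
    rad = HELIX_RADIUS + CB_OFFSET
    cb = np.stack([rad * np.cos(theta), rad * np.sin(theta), z], axis=1)
    return ca, cb


def _linker_positions(n: int, z0: float) -> tuple:
    """Extended, axis-hugging linker segment above height z0.

    A small lateral spiral (0.7 Å off the axis) keeps the segment extended
    while avoiding exact collinearity, which would introduce zero-energy
    mechanisms (spurious rigid-body modes) into the elastic network.
    """
    k = np.arange(1, n + 1)
    phi = 2.0 * k
    lateral = 0.7
    z = z0 + LINKER_SPACING * k
    ca = np.stack([lateral * np.cos(phi), lateral * np.sin(phi), z], axis=1)
    cb = ca + CB_OFFSET * np.stack([np.cos(phi), np.sin(phi), np.zeros(n)], axis=1)
    return ca, cb


def make_toy(spec: ToySpec) -> Structure:
    """Build the synthetic structure described by ``spec``.

    The result has one Cα and one CB per residue, interleaved per residue in
    chain order, and is deterministic: the same spec always yields
    bit-identical coordinates.
    """
    spec.validate()
    if spec.geometry == "helix":
        ca, cb = _helix_positions(spec.n_residues)
        segments = [(ca, cb)]
    else:
        n_dom2 = (spec.n_residues - spec.linker_length) // 2
        n_dom1 = spec.n_residues - spec.linker_length - n_dom2
        ca1, cb1 = _helix_positions(n_dom1)
        z_top = ca1[-1, 2]
        lca, lcb = _linker_positions(spec.linker_length, z_top)
        z2 = lca[-1, 2] + LINKER_SPACING
        ca2, cb2 = _helix_positions(n_dom2, z0=z2, phase=np.deg2rad(40.0))
        segments = [(ca1, cb1), (lca, lcb), (ca2, cb2)]

    names, resids, coords = [], [], []
    resid = 0
    for ca, cb in segments:
        for r in range(len(ca)):
            resid += 1
            names += ["CA", "CB"]
            resids += [resid, resid]
            coords += [ca[r], cb[r]]
    n_atoms = len(names)
    return Structure(
        atom_serial=np.arange(1, n_atoms + 1),
        atom_name=np.array(names, dtype=object),
        element=np.array(["C"] * n_atoms, dtype=object),
        residue_index=np.array(resids),
        residue_name=np.array(["ALA"] * n_atoms, dtype=object),
        chain_id=np.array(["A"] * n_atoms, dtype=object),
        coords=np.array(coords, dtype=float),
        coarse_grained=True,
    )


def domain_residue_ranges(spec: ToySpec) -> tuple:
    """(first, last) residue numbers of the two domains of a two_domain toy."""
    if spec.geometry != "two_domain":
        raise ContractError("domain ranges are defined for two_domain toys only")
    n_dom2 = (spec.n_residues - spec.linker_length) // 2
    n_dom1 = spec.n_residues - spec.linker_length - n_dom2
    dom1 = (1, n_dom1)
    dom2 = (n_dom1 + spec.linker_length + 1, spec.n_residues)
    return dom1, dom2
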