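"""Structures, atom selections and PDB/DCD input/output.

The PDB dialect is classic fixed-column: ``ATOM``/``HETATM`` records, first
MODEL only, alternate locations restricted to blank or ``'A'``, waters
dropped on read.  DCD output follows the CHARMM convention (32-bit record
markers, ``CORD`` tag, single-precision per-frame X/Y/Z arrays in Å) so any
mainstream trajectory reader can open it.
"""

from __future__ import annotations

import re
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .ensemble import Ensemble
from .errors import ContractError, FormatError, InputError, SelectionError

_WATER_RESNAMES = {"HOH", "WAT", "DOD", "TIP", "TIP3", "SPC"}


@dataclass
class Structure:
    """One biomolecular topology with a single set of coordinates (Å).

    ``(chain_id, residue_index, insertion code, atom_name)`` identifies an
    atom uniquely.  ``coarse_grained`` flags reduced representations (e.g.
    Cα+CB traces) for which chemical bond detection does not apply.
    """

    atom_serial: np.ndarray
    atom_name: np.ndarray
    element: np.ndarray
    residue_index: np.ndarray
    residue_name: np.ndarray
    chain_id: np.ndarray
    coords: np.ndarray
    coarse_grained: bool = False
    insertion_code: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        for attr in ("atom_serial", "residue_index"):
            setattr(self, attr, np.asarray(getattr(self, attr), dtype=int))
        for attr in ("atom_name", "element", "residue_name", "chain_id"):
            setattr(self, attr, np.asarray(getattr(self, attr), dtype=object))
        if self.insertion_code is None:
            self.insertion_code = np.full(self.n_atoms, "", dtype=object)
        else:
            self.insertion_code = np.asarray(self.insertion_code, dtype=object)
        self.validate()

    def validate(self) -> None:
        n = self.n_atoms
        if n < 3:
            raise ContractError(f"a structure needs at least 3 atoms, got {n}")
        if self.coords.shape != (n, 3) or not np.all(np.isfinite(self.coords)):
            raise ContractError("coords must be a finite (N, 3) matrix")
        keys = list(
            zip(self.chain_id, self.residue_index, self.insertion_code, self.atom_name)
        )
        if len(set(keys)) != n:
            raise ContractError(
                "(chain_id, residue_index, insertion code, atom_name) must be unique"
            )

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def residue_keys(self) -> list[tuple]:
        """Per-atom (chain, resid, icode) key identifying the parent residue."""
        return list(zip(self.chain_id, self.residue_index, self.insertion_code))

    def hydrogen_mask(self) -> np.ndarray:
        """True for hydrogen atoms, judged by element or, failing that, name."""
        mask = np.zeros(self.n_atoms, dtype=bool)
        for i in range(self.n_atoms):
            el = str(self.element[i]).strip().upper()
            if el:
                mask[i] = el == "H" or el == "D"
            else:
                name = str(self.atom_name[i]).strip().upper()
                stripped = name.lstrip("0123456789")
                mask[i] = stripped.startswith("H") or stripped.startswith("D")
        return mask

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Copy of this structure carrying new coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ContractError("replacement coords must match the atom count")
        return Structure(
            atom_serial=self.atom_serial.copy(),
            atom_name=self.atom_name.copy(),
            element=self.element.copy(),
            residue_index=self.residue_index.copy(),
            residue_name=self.residue_name.copy(),
            chain_id=self.chain_id.copy(),
            coords=coords.copy(),
            coarse_grained=self.coarse_grained,
            insertion_code=self.insertion_code.copy(),
        )


# ---------------------------------------------------------------------------
# PDB reading


def _guess_element(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return ""
    if stripped[0] in "HD" and len(name.strip()) <= 4:
        return "H" if stripped[0] == "H" else "D"
    return stripped[0]


def _looks_coarse_grained(names_by_residue: dict) -> bool:
    allowed = {"CA", "CB"}
    return all(set(names) <= allowed for names in names_by_residue.values())


def read_pdb(path) -> Structure:
    """Read the first model of a fixed-column PDB file.

    HETATM records are accepted; waters are dropped; alternate locations other
    than blank or 'A' are skipped.  Raises :class:`InputError` for a missing
    file and :class:`FormatError` for unparsable content (coordinate errors
    name the offending line number).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"PDB file not found: {path}")

    serials, names, elements, resids, resnames, chains, icodes, xyz = (
        [], [], [], [], [], [], [], [],
    )
    model_seen = 0
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            record = line[:6]
            if record.startswith("MODEL"):
                model_seen += 1
                if model_seen > 1:
                    break
                continue
            if record.startswith("ENDMDL"):
                break
            if record not in ("ATOM  ", "HETATM"):
                continue
            if len(line.rstrip("\n")) < 54:
                raise FormatError(
                    f"{path.name}: truncated atom record at line {lineno}"
                )
            altloc = line[16]
            if altloc not in (" ", "A"):
                continue
            resname = line[17:20].strip()
            if resname in _WATER_RESNAMES:
                continue
            try:
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except ValueError as exc:
                raise FormatError(
                    f"{path.name}: unparsable coordinate field at line {lineno}"
                ) from exc
            try:
                serial = int(line[6:11])
            except ValueError:
                serial = len(serials) + 1
            try:
                resid = int(line[22:26])
            except ValueError as exc:
                raise FormatError(
                    f"{path.name}: unparsable residue number at line {lineno}"
                ) from exc
            name = line[12:16].strip()
            element = line[76:78].strip() if len(line) >= 78 else ""
            serials.append(serial)
            names.append(name)
            elements.append(element or _guess_element(line[12:16]))
            resids.append(resid)
            resnames.append(resname)
            chains.append(line[21])
            icodes.append(line[26].strip())
            xyz.append((x, y, z))

    if not xyz:
        raise FormatError(f"{path.name}: no accepted ATOM/HETATM records")

    by_res: dict[tuple, list[str]] = {}
    for ch, ri, ic, nm in zip(chains, resids, icodes, names):
        by_res.setdefault((ch, ri, ic), []).append(nm)

    return Structure(
        atom_serial=np.array(serials),
        atom_name=np.array(names, dtype=object),
        element=np.array(elements, dtype=object),
        residue_index=np.array(resids),
        residue_name=np.array(resnames, dtype=object),
        chain_id=np.array(chains, dtype=object),
        coords=np.array(xyz, dtype=float),
        coarse_grained=_looks_coarse_grained(by_res),
        insertion_code=np.array(icodes, dtype=object),
    )


# ---------------------------------------------------------------------------
# PDB writing


def _format_atom_line(structure: Structure, i: int, coords: np.ndarray) -> str:
    name = str(structure.atom_name[i])
    # Standard PDB name justification: short names start in column 14.
    padded = name.ljust(3) if len(name) < 4 else name
    padded = (" " + padded) if len(padded) < 4 else padded
    serial = int(structure.atom_serial[i]) % 100000
    resid = int(structure.residue_index[i]) % 10000
    icode = str(structure.insertion_code[i]) or " "
    return (
        f"ATOM  {serial:5d} {padded:<4s} {str(structure.residue_name[i]):>3s} "
        f"{str(structure.chain_id[i]):1s}{resid:4d}{icode:1s}   "
        f"{coords[i, 0]:8.3f}{coords[i, 1]:8.3f}{coords[i, 2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {str(structure.element[i]):>2s}\n"
    )


def write_pdb(structure: Structure, path, ensemble: Ensemble | None = None) -> None:
    """Write a single-model PDB, or a multi-model PDB if an ensemble is given.

    Model order follows conformer order; coordinates are printed with three
    decimals (the format's precision).
    """
    if ensemble is not None and ensemble.n_atoms != structure.n_atoms:
        raise ContractError(
            f"ensemble atom count {ensemble.n_atoms} != structure atom "
            f"count {structure.n_atoms}"
        )
    path = Path(path)
    with open(path, "w") as handle:
        if ensemble is None:
            for i in range(structure.n_atoms):
                handle.write(_format_atom_line(structure, i, structure.coords))
            handle.write("END\n")
            return
        for m in range(ensemble.n_conformers):
            handle.write(f"MODEL {m + 1:8d}\n")
            for i in range(structure.n_atoms):
                handle.write(_format_atom_line(structure, i, ensemble.coords[m]))
            handle.write("ENDMDL\n")
        handle.write("END\n")


def read_pdb_models(path) -> np.ndarray:
    """Read all models of a multi-model PDB as an (M, N, 3) coordinate array."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"PDB file not found: {path}")
    models: list[list[tuple]] = []
    current: list[tuple] = []
    saw_model = False
    with open(path) as handle:
        for line in handle:
            record = line[:6]
            if record.startswith("MODEL"):
                saw_model = True
                current = []
            elif record.startswith("ENDMDL"):
                models.append(current)
            elif record in ("ATOM  ", "HETATM"):
                current.append(
                    (float(line[30:38]), float(line[38:46]), float(line[46:54]))
                )
    if not saw_model:
        models = [current]
    if not models or not models[0]:
        raise FormatError(f"{path.name}: no coordinate records")
    return np.array(models, dtype=float)


# ---------------------------------------------------------------------------
# DCD writing (CHARMM 32-bit convention)


def write_dcd(ensemble: Ensemble, path) -> None:
    """Write a CHARMM-style DCD trajectory (single precision, Å).

    Layout: each Fortran record is bracketed by 32-bit byte-count markers; the
    84-byte header block starts with the 'CORD' tag and carries the frame
    count; each frame stores X, Y and Z as separate float32 records.
    """
    if ensemble.n_conformers == 0:
        raise ContractError("cannot write a DCD with zero frames")
    m, n = ensemble.n_conformers, ensemble.n_atoms
    path = Path(path)
    with open(path, "wb") as fh:
        icntrl = [0] * 20
        icntrl[0] = m          # number of frames
        icntrl[1] = 1          # first step
        icntrl[2] = 1          # save frequency
        icntrl[3] = m          # total steps
        icntrl[19] = 24        # CHARMM version stamp (marks CHARMM dialect)
        header = b"CORD" + struct.pack("<9i", *icntrl[:9])
        header += struct.pack("<f", 1.0)           # timestep (CHARMM float)
        header += struct.pack("<10i", *icntrl[10:])
        fh.write(struct.pack("<i", len(header)) + header + struct.pack("<i", len(header)))

        title = b"Created by enmsampler".ljust(80)
        block = struct.pack("<i", 1) + title
        fh.write(struct.pack("<i", len(block)) + block + struct.pack("<i", len(block)))

        fh.write(struct.pack("<i", 4) + struct.pack("<i", n) + struct.pack("<i", 4))

        marker = struct.pack("<i", 4 * n)
        for frame in ensemble.coords:
            frame32 = np.ascontiguousarray(frame, dtype="<f4")
            for axis in range(3):
                fh.write(marker)
                fh.write(frame32[:, axis].tobytes())
                fh.write(marker)


def read_dcd(path) -> np.ndarray:
    """Read a CHARMM-style DCD written by :func:`write_dcd` → (M, N, 3) Å."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"DCD file not found: {path}")
    with open(path, "rb") as fh:
        def record():
            head = fh.read(4)
            if len(head) < 4:
                return None
            (size,) = struct.unpack("<i", head)
            payload = fh.read(size)
            tail = fh.read(4)
            if len(payload) < size or struct.unpack("<i", tail)[0] != size:
                raise FormatError(f"{path.name}: corrupt record marker")
            return payload

        header = record()
        if header is None or len(header) != 84 or header[:4] != b"CORD":
            raise FormatError(f"{path.name}: not a CHARMM DCD header")
        n_frames = struct.unpack("<i", header[4:8])[0]
        record()  # title block
        natom_block = record()
        (n_atoms,) = struct.unpack("<i", natom_block)
        frames = np.empty((n_frames, n_atoms, 3))
        for m in range(n_frames):
            for axis in range(3):
                data = record()
                if data is None or len(data) != 4 * n_atoms:
                    raise FormatError(f"{path.name}: truncated frame {m}")
                frames[m, :, axis] = np.frombuffer(data, dtype="<f4")
    return frames


# ---------------------------------------------------------------------------
# Atom selections

_GRAMMAR = (
    "supported selection grammar: 'calpha' | 'chain <id>' | "
    "'resid <a>-<b>' | 'name <atomname>' | conjunctions joined by 'and'"
)


def _clause_mask(structure: Structure, clause: str) -> np.ndarray:
    clause = clause.strip()
    if clause == "calpha":
        return np.array([str(n) == "CA" for n in structure.atom_name])
    m = re.fullmatch(r"chain\s+(\S)", clause)
    if m:
        return np.array([str(c) == m.group(1) for c in structure.chain_id])
    m = re.fullmatch(r"resid\s+(-?\d+)\s*-\s*(-?\d+)", clause)
    if m:
        lo, hi = int(m.group(1)), int(m.group(2))
        return (structure.residue_index >= lo) & (structure.residue_index <= hi)
    m = re.fullmatch(r"name\s+(\S+)", clause)
    if m:
        return np.array([str(n) == m.group(1) for n in structure.atom_name])
    raise SelectionError(f"unsupported selection clause {clause!r}; {_GRAMMAR}")


def select(structure: Structure, expression: str) -> np.ndarray:
    """Evaluate a selection expression to a boolean mask over atoms.

    The grammar is deliberately small: ``calpha``, ``chain <id>``,
    ``resid <a>-<b>``, ``name <atomname>`` and ``and``-conjunctions thereof.
    An empty result is returned as an all-False mask; operations that need
    atoms raise on it downstream.
    """
    if not isinstance(expression, str) or not expression.strip():
        raise SelectionError(f"empty selection expression; {_GRAMMAR}")
    mask = np.ones(structure.n_atoms, dtype=bool)
    for clause in expression.split(" and "):
        mask &= _clause_mask(structure, clause)
    return mask
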