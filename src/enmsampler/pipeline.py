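"""Generation loop: sample → cluster → relax → feed back.

Each generation deforms every parent conformer along its own current global
modes, pools all children, clusters them by pairwise Cα RMSD, relaxes the
cluster medoids and feeds those back as the next generation's parents.  The
input structure is relaxed once before sampling starts, so deformations
begin from a local minimum of the restraint energy.

Random streams are derived per (master_seed, generation, parent), so runs
are bit-reproducible and independent of parent processing order; a run
record checkpointed after every generation makes interrupted runs
resumable with identical results.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .anm import AnmParams, compute_anm_modes, node_mask_for
from .clustering import ClusterParams, cluster, pairwise_rmsd, representatives
from .ensemble import Ensemble
from .errors import ConfigurationError, ContractError, PipelineError, ResumeError
from .relaxation import RelaxParams, build_bond_list, relax, relax_external
from .sampling import SamplingParams, child_rng, generate_conformers
from .structure_io import Structure, write_dcd, write_pdb

logger = logging.getLogger("enmsampler.pipeline")

RECORD_FILENAME = "record.json"
INCOMPLETE_MARKER = "RUN_INCOMPLETE"


@dataclass
class PipelineConfig:
    """All pipeline tunables in one place."""

    n_gens: int = 5
    sampling: SamplingParams = field(default_factory=SamplingParams)
    anm: AnmParams = field(default_factory=AnmParams)
    cluster: ClusterParams = field(default_factory=ClusterParams)
    relax: RelaxParams = field(default_factory=RelaxParams)
    recompute_modes_each_generation: bool = True
    output_dir: str | None = None
    output_formats: tuple = ("pdb",)
    master_seed: int = 0
    adapter_config: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_gens < 1:
            raise ContractError("n_gens must be >= 1")
        formats = tuple(self.output_formats)
        if not formats or not set(formats) <= {"pdb", "dcd"}:
            raise ConfigurationError(
                "output_formats must be a non-empty subset of {'pdb', 'dcd'}"
            )
        self.sampling.validate()
        self.anm.validate()
        self.cluster.validate()
        self.relax.validate()

    def snapshot(self) -> dict:
        snap = asdict(self)
        snap["output_formats"] = list(self.output_formats)
        return snap


def config_from_dict(flat: dict) -> PipelineConfig:
    """Build a config from flat key/value pairs (config-file & CLI surface).

    Recognized keys: n_gens, n_confs, target_rmsd, n_modes, cutoff, gamma,
    cluster_mode, maxclust, threshold, linkage, backend, adapter, k_bond,
    k_rep, rep_cutoff, bond_detect_max, step_size, max_steps, force_tol,
    recompute_modes_each_generation, output_dir, output_formats, seed.
    """
    flat = dict(flat)
    config = PipelineConfig()
    simple = {
        "n_gens": ("n_gens", int),
        "recompute_modes_each_generation": ("recompute_modes_each_generation", bool),
        "output_dir": ("output_dir", str),
        "seed": ("master_seed", int),
    }
    sub = {
        "n_confs": (config.sampling, "n_confs", int),
        "target_rmsd": (config.sampling, "target_rmsd", float),
        "n_modes": (config.anm, "n_modes", int),
        "cutoff": (config.anm, "cutoff", float),
        "gamma": (config.anm, "gamma", float),
        "cluster_mode": (config.cluster, "mode", str),
        "maxclust": (config.cluster, "maxclust", int),
        "threshold": (config.cluster, "threshold", float),
        "linkage": (config.cluster, "linkage", str),
        "backend": (config.relax, "backend", str),
        "k_bond": (config.relax, "k_bond", float),
        "k_rep": (config.relax, "k_rep", float),
        "rep_cutoff": (config.relax, "rep_cutoff", float),
        "bond_detect_max": (config.relax, "bond_detect_max", float),
        "step_size": (config.relax, "step_size", float),
        "max_steps": (config.relax, "max_steps", int),
        "force_tol": (config.relax, "force_tol", float),
    }
    for key, value in flat.items():
        if value is None:
            continue
        if key == "output_formats":
            if isinstance(value, str):
                value = [v.strip() for v in value.split(",") if v.strip()]
            config.output_formats = tuple(value)
        elif key == "adapter":
            config.adapter_config = {**config.adapter_config, "adapter": value}
        elif key == "adapter_config":
            config.adapter_config = {**dict(value), **config.adapter_config}
        elif key in simple:
            attr, cast = simple[key]
            setattr(config, attr, cast(value))
        elif key in sub:
            obj, attr, cast = sub[key]
            setattr(obj, attr, cast(value))
        else:
            raise ConfigurationError(f"unknown configuration key {key!r}")
    return config


@dataclass
class RunRecord:
    """Machine-readable account of one run, sufficient to resume it."""

    master_seed: int
    config: dict
    structure: dict
    generations: list = field(default_factory=list)
    checkpoints: list = field(default_factory=list)  # [g][rep][atom][xyz]
    lineage: list = field(default_factory=list)      # [(generation, parent)]
    timestamps: dict = field(default_factory=dict)
    completed: bool = False

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "RunRecord":
        return cls(**json.loads(text))


def _structure_to_dict(structure: Structure) -> dict:
    return {
        "atom_serial": structure.atom_serial.tolist(),
        "atom_name": structure.atom_name.tolist(),
        "element": structure.element.tolist(),
        "residue_index": structure.residue_index.tolist(),
        "residue_name": structure.residue_name.tolist(),
        "chain_id": structure.chain_id.tolist(),
        "coords": structure.coords.tolist(),
        "coarse_grained": structure.coarse_grained,
        "insertion_code": structure.insertion_code.tolist(),
    }


def _structure_from_dict(data: dict) -> Structure:
    return Structure(
        atom_serial=np.array(data["atom_serial"]),
        atom_name=np.array(data["atom_name"], dtype=object),
        element=np.array(data["element"], dtype=object),
        residue_index=np.array(data["residue_index"]),
        residue_name=np.array(data["residue_name"], dtype=object),
        chain_id=np.array(data["chain_id"], dtype=object),
        coords=np.array(data["coords"], dtype=float),
        coarse_grained=data["coarse_grained"],
        insertion_code=np.array(data["insertion_code"], dtype=object),
    )


def _relax_one(
    structure: Structure,
    coords: np.ndarray,
    bonds: list,
    config: PipelineConfig,
    context: str,
):
    if config.relax.backend == "external":
        return relax_external(coords, structure, config.adapter_config, context=context)
    return relax(coords, bonds, config.relax, heavy_mask=~structure.hydrogen_mask())


def _write_record(record: RunRecord, output_dir: Path | None) -> None:
    if output_dir is None:
        return
    output_dir.mkdir(parents=True, exist_ok=True)
    (output_dir / RECORD_FILENAME).write_text(record.to_json())


def _mark_incomplete(output_dir: Path | None, context: str) -> None:
    if output_dir is None:
        return
    output_dir.mkdir(parents=True, exist_ok=True)
    (output_dir / INCOMPLETE_MARKER).write_text(context + "\n")


def _assemble_ensemble(record: RunRecord) -> Ensemble:
    coords, gens, parents = [], [], []
    for g, reps in enumerate(record.checkpoints):
        if g == 0:
            continue  # generation 0 is the relaxed input, not an output conformer
        for r, rep in enumerate(reps):
            coords.append(rep)
            gens.append(g)
            parents.append(record.generations[g - 1]["rep_parents"][r])
    return Ensemble(
        coords=np.array(coords, dtype=float),
        generation=np.array(gens, dtype=int),
        parent=np.array(parents, dtype=int),
    )


def _write_outputs(structure: Structure, ensemble: Ensemble, config: PipelineConfig) -> None:
    if config.output_dir is None:
        return
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if "pdb" in config.output_formats:
        write_pdb(structure, out / "ensemble.pdb", ensemble)
    if "dcd" in config.output_formats:
        write_dcd(ensemble, out / "ensemble.dcd")


def _run_generations(
    structure: Structure,
    config: PipelineConfig,
    record: RunRecord,
    start_gen: int,
) -> tuple[Ensemble, RunRecord]:
    """Advance the loop from ``start_gen`` to ``n_gens`` (inclusive)."""
    output_dir = Path(config.output_dir) if config.output_dir else None
    ca_mask = node_mask_for(structure)
    bonds = build_bond_list(structure, config.relax)
    modes_input = None

    parents = np.array(record.checkpoints[start_gen - 1], dtype=float)
    stage = "setup"
    g = start_gen
    try:
        for g in range(start_gen, config.n_gens + 1):
            t0 = time.time()
            stage = "sampling"
            pool_parts, pool_parents = [], []
            for p_idx in range(len(parents)):
                if config.recompute_modes_each_generation:
                    basis = compute_anm_modes(structure, config.anm, coords=parents[p_idx])
                else:
                    if modes_input is None:
                        modes_input = compute_anm_modes(
                            structure, config.anm, coords=np.array(record.checkpoints[0][0])
                        )
                    basis = modes_input
                ens = generate_conformers(
                    parents[p_idx],
                    basis,
                    ca_mask,
                    config.sampling,
                    rng=child_rng(config.master_seed, g, p_idx),
                    generation=g,
                    parent_index=p_idx,
                )
                pool_parts.append(ens.coords)
                pool_parents.extend([p_idx] * len(ens))
            pool = Ensemble(
                coords=np.concatenate(pool_parts, axis=0),
                generation=np.full(len(pool_parents), g, dtype=int),
                parent=np.array(pool_parents, dtype=int),
            )
            logger.info("generation %d: sampled %d conformers from %d parents",
                        g, len(pool), len(parents))

            stage = "clustering"
            dist = pairwise_rmsd(pool, ca_mask)
            cres = representatives(dist, cluster(dist, config.cluster))
            logger.info("generation %d: %d clusters", g, cres.n_clusters)

            stage = "relaxation"
            rep_coords, rep_parents = [], []
            for r in cres.representatives:
                result = _relax_one(
                    structure, pool.coords[r], bonds, config,
                    context=f"generation {g}, conformer {int(r)}",
                )
                rep_coords.append(result.coords.tolist())
                rep_parents.append(int(pool.parent[r]))

            record.generations.append(
                {
                    "generation": g,
                    "parents": len(parents),
                    "conformers": len(pool),
                    "clusters": int(cres.n_clusters),
                    "representatives": len(rep_coords),
                    "rep_parents": rep_parents,
                    "seconds": round(time.time() - t0, 3),
                }
            )
            record.checkpoints.append(rep_coords)
            record.lineage.extend((g, p) for p in rep_parents)
            parents = np.array(rep_coords, dtype=float)
            _write_record(record, output_dir)
    except Exception as exc:
        context = f"generation {g}, stage {stage}: {exc}"
        _write_record(record, output_dir)
        _mark_incomplete(output_dir, context)
        raise PipelineError(f"pipeline aborted at {context}") from exc

    record.completed = True
    record.timestamps["end"] = time.time()
    ensemble = _assemble_ensemble(record)
    _write_outputs(structure, ensemble, config)
    _write_record(record, output_dir)
    if output_dir is not None and (output_dir / INCOMPLETE_MARKER).exists():
        (output_dir / INCOMPLETE_MARKER).unlink()
    return ensemble, record


def run(structure: Structure, config: PipelineConfig | None = None) -> tuple[Ensemble, RunRecord]:
    """Execute the full iterative sampling pipeline.

    Returns the concatenated ensemble of all generations' relaxed
    representatives (with generation and parent lineage) and the run record.
    """
    config = config or PipelineConfig()
    config.validate()
    structure.validate()
    output_dir = Path(config.output_dir) if config.output_dir else None

    record = RunRecord(
        master_seed=config.master_seed,
        config=config.snapshot(),
        structure=_structure_to_dict(structure),
        timestamps={"start": time.time()},
    )
    bonds = build_bond_list(structure, config.relax)
    try:
        relax0 = _relax_one(structure, structure.coords, bonds, config, context="input")
    except Exception as exc:
        _mark_incomplete(output_dir, f"generation 0, stage relaxation: {exc}")
        raise PipelineError(f"pipeline aborted at input relaxation: {exc}") from exc
    record.checkpoints.append([np.asarray(relax0.coords).tolist()])
    _write_record(record, output_dir)
    logger.info("input structure relaxed (%d atoms); starting %d generations",
                structure.n_atoms, config.n_gens)
    return _run_generations(structure, config, record, start_gen=1)


def load_record(output_dir) -> RunRecord:
    path = Path(output_dir) / RECORD_FILENAME
    if not path.exists():
        raise ResumeError(f"no run record found at {path}")
    return RunRecord.from_json(path.read_text())


def _diff_config(stored: dict, requested: dict, prefix: str = "") -> list[str]:
    diffs = []
    for key in sorted(set(stored) | set(requested)):
        a, b = stored.get(key), requested.get(key)
        name = f"{prefix}{key}"
        if isinstance(a, dict) and isinstance(b, dict):
            diffs.extend(_diff_config(a, b, prefix=name + "."))
        elif a != b:
            diffs.append(f"{name}: stored={a!r} requested={b!r}")
    return diffs


def resume(output_dir, config: PipelineConfig | None = None) -> tuple[Ensemble, RunRecord]:
    """Continue an interrupted run from its last completed generation.

    The stored config snapshot is authoritative; passing a ``config`` that
    differs from it is refused with a field-by-field diff.  A completed run
    resumes as a no-op returning the stored results.
    """
    record = load_record(output_dir)
    stored_config = config_from_snapshot(record.config)
    if config is not None:
        diffs = _diff_config(record.config, config.snapshot())
        diffs = [d for d in diffs if not d.startswith("output_dir")]
        if diffs:
            raise ResumeError(
                "resume config differs from the stored snapshot:\n  "
                + "\n  ".join(diffs)
            )
    stored_config.output_dir = str(output_dir)
    structure = _structure_from_dict(record.structure)

    if record.completed:
        return _assemble_ensemble(record), record

    completed_gens = len(record.checkpoints) - 1  # checkpoint 0 is the input
    if completed_gens < 0:
        raise ResumeError("stored record has no generation-0 checkpoint")
    marker = Path(output_dir) / INCOMPLETE_MARKER
    if marker.exists():
        marker.unlink()
    # Drop any partially recorded generations beyond the last checkpoint.
    record.generations = record.generations[:completed_gens]
    record.lineage = [tuple(x) for x in record.lineage][: sum(
        g["representatives"] for g in record.generations
    )]
    logger.info("resuming after generation %d of %d", completed_gens, stored_config.n_gens)
    return _run_generations(structure, stored_config, record, start_gen=completed_gens + 1)


def config_from_snapshot(snapshot: dict) -> PipelineConfig:
    """Rebuild a PipelineConfig from a record's config snapshot."""
    snap = dict(snapshot)
    return PipelineConfig(
        n_gens=snap["n_gens"],
        sampling=SamplingParams(**snap["sampling"]),
        anm=AnmParams(**snap["anm"]),
        cluster=ClusterParams(**snap["cluster"]),
        relax=RelaxParams(**snap["relax"]),
        recompute_modes_each_generation=snap["recompute_modes_each_generation"],
        output_dir=snap["output_dir"],
        output_formats=tuple(snap["output_formats"]),
        master_seed=snap["master_seed"],
        adapter_config=dict(snap["adapter_config"]),
    )
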