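"""The four prediction task types and batch mode.

Task types mirror the web-service workflow this tool replaces:

1. ``assemble``       - template assembly only (fast);
2. ``sample``         - assembly + template-swap sampling + clustering;
3. ``optimize``       - assembly + restraint-guided SAMC refinement
                        (pseudoknot pairs become restraints automatically);
4. ``optimize_only``  - SAMC refinement of an uploaded model.

Each task writes ranked PDB models plus a JSON manifest with full
provenance (template sources, seeds, scores, cluster sizes, restraint
report).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .analysis import kmeans_rmsd, rank_centroids, score_structure
from .assembler import PredictionConfig, assemble_top, relax, sample_templates
from .conformation import Conformation
from .optimizer import (
    AnnealSchedule,
    OptimizerEnergy,
    Restraint,
    read_restraints,
    restraint_violation,
    restraints_from_pseudoknot,
    samc_optimize,
)
from .pdbio import read_pdb, write_pdb
from .secstruct import (
    SecondaryStructure,
    decompose_sse,
    movable_elements,
    parse_dotbracket,
    split_pseudoknots,
)
from .templates import TemplateLibrary

__all__ = ["TaskSpec", "run_task", "run_batch", "expand_batch", "validate_manifest"]

log = logging.getLogger(__name__)

TASK_TYPES = ("assemble", "sample", "optimize", "optimize_only")


@dataclass
class TaskSpec:
    """One prediction task."""

    task_type: str
    name: str = "task"
    sequence: str | None = None
    dotbracket: str | None = None
    model_path: str | None = None
    restraints: list[Restraint] = field(default_factory=list)
    restraints_path: str | None = None
    config: PredictionConfig = field(default_factory=PredictionConfig)
    library: TemplateLibrary | None = None
    outdir: str = "."
    schedule: AnnealSchedule = field(default_factory=AnnealSchedule)
    energy: OptimizerEnergy = field(default_factory=OptimizerEnergy)

    def __post_init__(self) -> None:
        if self.task_type not in TASK_TYPES:
            raise ValueError(f"unknown task type {self.task_type!r}")
        if self.task_type == "optimize_only":
            if not self.model_path:
                raise ValueError("optimize_only requires a model file")
        elif not (self.sequence and self.dotbracket):
            raise ValueError(f"task {self.task_type!r} requires sequence and structure")


def _gather_restraints(spec: TaskSpec, ss: SecondaryStructure) -> list[Restraint]:
    out = list(spec.restraints)
    if spec.restraints_path:
        out.extend(read_restraints(spec.restraints_path))
    if spec.task_type in ("optimize", "optimize_only") and ss.pk_pairs:
        auto = restraints_from_pseudoknot(ss.pk_pairs)
        log.info("converted %d pseudoknot pairs to restraints", len(auto))
        out.extend(auto)
    return out


def run_task(spec: TaskSpec) -> dict:
    """Execute one task; returns (and writes) the result manifest."""
    t_start = time.time()
    outdir = Path(spec.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = spec.config
    lib = spec.library or TemplateLibrary()

    if spec.task_type == "optimize_only":
        conf = read_pdb(spec.model_path)
        if spec.dotbracket:
            ss = parse_dotbracket(spec.dotbracket, conf.sequence)
        else:
            from .analysis import annotate_interactions

            nested, pk = split_pseudoknots(annotate_interactions(conf).wc_pairs)
            ss = SecondaryStructure(conf.sequence, nested, pk)
        models, extra = _optimize_models([conf], spec, ss)
    else:
        ss = parse_dotbracket(spec.dotbracket, spec.sequence)
        if ss.pk_pairs and spec.task_type in ("assemble", "sample"):
            log.warning(
                "%d pseudoknot pairs are ignored by task %r; use the "
                "optimization task to realize them as restraints",
                len(ss.pk_pairs),
                spec.task_type,
            )
        tree = decompose_sse(ss)
        if spec.task_type == "assemble":
            models = assemble_top(tree, lib, ss, cfg)
            extra = {}
        elif spec.task_type == "sample":
            ensemble = sample_templates(tree, lib, ss, cfg)
            k = min(cfg.n_predictions, len(ensemble))
            clusters = kmeans_rmsd(ensemble, k, seed=cfg.seed)
            models = rank_centroids(clusters, ensemble)
            if cfg.refine:
                models = [relax(m, ss=ss) for m in models]
            extra = {"ensemble_size": len(ensemble), "cluster_sizes": clusters.sizes}
        else:  # optimize
            starts = assemble_top(tree, lib, ss, cfg)
            models, extra = _optimize_models(starts, spec, ss)

    records = []
    for rank, m in enumerate(models, start=1):
        path = outdir / f"{spec.name}_model{rank}.pdb"
        write_pdb(m, path)
        records.append(
            {
                "rank": rank,
                "file": path.name,
                "score": score_structure(m),
                "provenance": m.provenance,
            }
        )
    manifest = {
        "name": spec.name,
        "task_type": spec.task_type,
        "sequence": ss.sequence,
        "n_predictions": cfg.n_predictions,
        "sampling_steps": cfg.sampling_steps,
        "seed": cfg.seed,
        "n_pseudoknot_pairs": len(ss.pk_pairs),
        "restraints": [
            {"kind": r.kind, "i": r.i + 1, "j": r.j + 1, "weight": r.weight}
            for r in _gather_restraints(spec, ss)
        ],
        "models": records,
        "wall_time_s": round(time.time() - t_start, 3),
        **extra,
    }
    validate_manifest(manifest)
    (outdir / f"{spec.name}_manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _optimize_models(
    starts: list[Conformation], spec: TaskSpec, ss: SecondaryStructure
) -> tuple[list[Conformation], dict]:
    nested = SecondaryStructure(ss.sequence, ss.pairs)
    restraints = _gather_restraints(spec, ss)
    elements = movable_elements(nested)
    cfg = spec.config
    optimized = []
    for k, start in enumerate(starts):
        result = samc_optimize(
            start,
            elements,
            restraints,
            spec.schedule,
            spec.energy,
            seed=cfg.seed + k,
            ss=nested,
        )
        best = result.best
        if cfg.refine:
            best = relax(best, ss=nested, restraints=restraints)
        best.provenance["samc"] = {
            "seed": cfg.seed + k,
            "acceptance_ratio": round(result.acceptance_ratio, 4),
            "best_energy": result.best_energy,
            "restraint_violations": [
                round(restraint_violation(best, r), 3) for r in restraints
            ],
        }
        optimized.append(best)
    optimized.sort(key=score_structure)
    return optimized, {"n_restraints": len(restraints)}


# ---------------------------------------------------------------------------
# batch mode


def expand_batch(sequences: list[str], structures: list[str]) -> list[tuple[str, str]]:
    """Pair up batch inputs.

    Mode A: one sequence with many structures; mode B: equally many
    sequences and structures, paired line by line.
    """
    sequences = [s.strip() for s in sequences if s.strip()]
    structures = [s.strip() for s in structures if s.strip()]
    if not sequences or not structures:
        raise ValueError("batch input needs at least one sequence and one structure")
    if len(sequences) == 1:
        return [(sequences[0], st) for st in structures]
    if len(sequences) != len(structures):
        raise ValueError(
            "sequence and structure lists should contain the same number of lines "
            f"(got {len(sequences)} and {len(structures)})"
        )
    return list(zip(sequences, structures))


def run_batch(
    sequences: list[str],
    structures: list[str],
    template: TaskSpec,
) -> list[dict]:
    """One task per batch pairing; seeds derived from the master seed."""
    out = []
    for k, (seq, db) in enumerate(expand_batch(sequences, structures)):
        cfg = PredictionConfig(
            n_predictions=template.config.n_predictions,
            sampling_steps=template.config.sampling_steps,
            seed=(template.config.seed + 1000003 * (k + 1)) % (2**31 - 1),
            exclude_ids=set(template.config.exclude_ids),
            refine=template.config.refine,
        )
        spec = TaskSpec(
            task_type=template.task_type,
            name=f"{template.name}_{k + 1}",
            sequence=seq,
            dotbracket=db,
            restraints=list(template.restraints),
            restraints_path=template.restraints_path,
            config=cfg,
            library=template.library,
            outdir=template.outdir,
            schedule=template.schedule,
            energy=template.energy,
        )
        out.append(run_task(spec))
    return out


# ---------------------------------------------------------------------------
# manifest schema (shipped, minimal)

MANIFEST_SCHEMA = {
    "required": {
        "name": str,
        "task_type": str,
        "sequence": str,
        "n_predictions": int,
        "sampling_steps": int,
        "seed": int,
        "n_pseudoknot_pairs": int,
        "restraints": list,
        "models": list,
        "wall_time_s": float,
    },
    "model_required": {"rank": int, "file": str, "score": float},
}


def validate_manifest(manifest: dict) -> None:
    """Check a manifest against the shipped schema; raises on mismatch."""
    for key, typ in MANIFEST_SCHEMA["required"].items():
        if key not in manifest:
            raise ValueError(f"manifest missing key {key!r}")
        if not isinstance(manifest[key], typ):
            raise ValueError(f"manifest key {key!r} has wrong type")
    for m in manifest["models"]:
        for key, typ in MANIFEST_SCHEMA["model_required"].items():
            if key not in m or not isinstance(m[key], typ):
                raise ValueError(f"model record missing/bad key {key!r}")
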