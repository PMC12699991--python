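"""End-to-end pipeline driver: prep -> plan -> dock -> aggregate -> score ->
validate -> report, with marker-based resume at the docking stage.

The run directory layout:

    work_dir/
      prepared/        trimmed PDB, receptor/ligand PDBQT, box files
      results/         per-job Vina-style output files
      done/            zero-byte completion markers
      matrix/          energy matrix + provenance TSV
      reports/         candidate tables, summary, score distributions
      seed_manifest.tsv
      provenance.json
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import aggregation, docking, scoring, validation
from .config import RunConfig
from .errors import VinascreenError
from .fixtures import MockLandscape
from .formats import (
    read_pdb,
    read_sdf_v2000,
    write_pdb,
    write_pdbqt_ligand,
    write_pdbqt_receptor,
)
from .ligand_prep import prepare_ligand
from .receptor_prep import SearchBox, prepare_receptor

log = logging.getLogger("vinascreen")


@dataclass
class PipelineResult:
    work_dir: Path
    matrix: aggregation.EnergyMatrix
    z_scores: scoring.NormalizedScores
    mm_scores: scoring.NormalizedScores
    z_selection: scoring.SelectionResult
    mm_selection: scoring.SelectionResult
    labeled: list[validation.LabeledCandidate]
    thresholds: validation.PriorityThresholds | None
    novel_by_energy: list[validation.LabeledCandidate]
    novel_by_minmax: list[validation.LabeledCandidate]
    report: validation.ReportBundle
    counts: dict[str, object] = field(default_factory=dict)


def _load_two_column_tsv(path: str) -> dict[str, str]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.shape[1] < 2:
        raise VinascreenError(f"mapping file {path!r} needs two columns")
    return dict(zip(frame.iloc[:, 0], frame.iloc[:, 1]))


def prepare_receptors_stage(config: RunConfig, prepared_dir: Path):
    """Read, trim, charge and box every receptor PDB in the input directory."""
    receptors_dir = Path(config.paths.receptors_dir)
    pdb_files = sorted(receptors_dir.glob("*.pdb"))
    if not pdb_files:
        raise VinascreenError(f"no .pdb files in {receptors_dir}")
    boxes: dict[str, SearchBox] = {}
    receptor_paths: dict[str, Path] = {}
    trim_counts = {}
    for path in pdb_files:
        rid = path.stem
        structure = read_pdb(path.read_text(), receptor_id=rid,
                             alphafold_sourced=config.receptor_prep.alphafold)
        trimmed, box, report = prepare_receptor(
            structure,
            plddt_threshold=config.receptor_prep.plddt_threshold,
            box_margin=config.docking.box_margin,
        )
        (prepared_dir / f"{rid}.trimmed.pdb").write_text(write_pdb(trimmed))
        out = prepared_dir / f"{rid}.pdbqt"
        out.write_text(write_pdbqt_receptor(trimmed))
        (prepared_dir / f"{rid}.box").write_text(box.to_key_value())
        boxes[rid] = box
        receptor_paths[rid] = out
        trim_counts[rid] = {"kept": report.total_kept, "removed": report.total_removed}
        log.info("prep-receptor %s kept=%d removed=%d", rid,
                 report.total_kept, report.total_removed)
    return boxes, receptor_paths, trim_counts


def prepare_ligands_stage(config: RunConfig, prepared_dir: Path):
    ligands_dir = Path(config.paths.ligands_dir)
    sdf_files = sorted(ligands_dir.glob("*.sdf"))
    if not sdf_files:
        raise VinascreenError(f"no .sdf files in {ligands_dir}")
    ligand_paths: dict[str, Path] = {}
    for path in sdf_files:
        lid = path.stem
        ligand = prepare_ligand(read_sdf_v2000(path.read_text()), ligand_id=lid)
        out = prepared_dir / f"{lid}.pdbqt"
        out.write_text(write_pdbqt_ligand(ligand))
        ligand_paths[lid] = out
        log.info("prep-ligand %s torsions=%d", lid, len(ligand.rotatable_bonds))
    return ligand_paths


def _resolve_backend(config: RunConfig):
    if config.docking.backend == "mock":
        if not config.paths.landscape:
            raise VinascreenError("mock backend requires paths.landscape")
        landscape = MockLandscape.from_json(Path(config.paths.landscape).read_text())
        return docking.MockBackend(landscape)
    if config.docking.backend == "vina":
        return docking.ExternalVinaBackend(config.docking.vina_executable)
    raise VinascreenError(f"unknown backend {config.docking.backend!r}")


def plan_jobs(
    config: RunConfig,
    receptor_ids: list[str],
    ligand_ids: list[str],
    boxes: dict[str, SearchBox] | None,
    work_dir: Path,
    receptor_paths: dict[str, Path] | None = None,
    ligand_paths: dict[str, Path] | None = None,
) -> list[docking.DockingJob]:
    jobs = docking.enumerate_jobs(
        receptor_ids, ligand_ids,
        replicates=config.docking.replicates,
        master_seed=config.docking.master_seed,
        box_of=boxes,
        exhaustiveness=config.docking.exhaustiveness,
        cpu=config.docking.cpu,
        num_modes=config.docking.num_modes,
    )
    results_dir = work_dir / "results"
    results_dir.mkdir(parents=True, exist_ok=True)
    for job in jobs:
        job.out_path = str(results_dir / f"{job.key}.pdbqt")
        job.config_path = str(work_dir / "configs" / f"{job.key}.txt")
        if receptor_paths:
            job.receptor_path = str(receptor_paths[job.receptor_id])
        if ligand_paths:
            job.ligand_path = str(ligand_paths[job.ligand_id])
    docking.write_seed_manifest(jobs, work_dir / "seed_manifest.tsv")
    return jobs


def run_pipeline(config: RunConfig, skip_prep: bool = False) -> PipelineResult:
    """Execute the whole campaign; resumable at the docking stage.

    ``skip_prep`` runs directly from receptor/ligand id lists taken from the
    mock landscape (no structure files needed) — the mode used for pure
    score-pipeline simulations.
    """
    work_dir = Path(config.paths.work_dir)
    work_dir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, object] = {}

    backend = _resolve_backend(config)

    if skip_prep:
        if not isinstance(backend, docking.MockBackend):
            raise VinascreenError("skip_prep requires the mock backend")
        landscape = backend.landscape
        receptor_ids = list(landscape.receptor_ids)
        ligand_ids = list(landscape.ligand_ids)
        boxes = None
        receptor_paths = ligand_paths = None
    else:
        prepared_dir = work_dir / "prepared"
        prepared_dir.mkdir(exist_ok=True)
        boxes, receptor_paths, trim_counts = prepare_receptors_stage(config, prepared_dir)
        ligand_paths = prepare_ligands_stage(config, prepared_dir)
        receptor_ids = sorted(boxes)
        ligand_ids = sorted(ligand_paths)
        counts["trim"] = trim_counts

    jobs = plan_jobs(config, receptor_ids, ligand_ids, boxes, work_dir,
                     receptor_paths, ligand_paths)
    counts["jobs"] = len(jobs)
    counts["pairs"] = len(receptor_ids) * len(ligand_ids)

    ledger = docking.CheckpointLedger(work_dir / "done")
    results = docking.run_queue(jobs, backend, ledger, workers=config.docking.workers)
    counts["completed_jobs"] = sum(1 for r in results.values() if r.status == "ok")
    counts["failed_jobs"] = sum(1 for r in results.values() if r.status != "ok")

    matrix, masked = aggregation.build_matrix(results, jobs)
    counts["masked_cells"] = masked
    matrix_dir = work_dir / "matrix"
    matrix_dir.mkdir(exist_ok=True)
    matrix.write_tsv(matrix_dir / "energy_matrix.tsv", matrix_dir / "provenance.tsv")

    z_scores = scoring.zscore_normalize(matrix, ddof=config.scoring.sd_ddof)
    mm_scores = scoring.minmax_normalize(matrix)
    z_selection = scoring.select_outliers_z(z_scores, threshold=config.scoring.z_threshold)
    mm_selection = scoring.select_outliers_minmax(
        mm_scores, fraction=config.scoring.minmax_fraction,
        per_row=config.scoring.minmax_per_row,
    )

    reports_dir = work_dir / "reports"
    reports_dir.mkdir(exist_ok=True)
    for scores in (z_scores, mm_scores):
        values = scores.values[~np.isnan(scores.values)]
        fit = scoring.fit_gaussian(values)
        frame = pd.DataFrame({
            "bin_left": fit.bin_edges[:-1], "bin_right": fit.bin_edges[1:],
            "count": fit.counts,
        })
        frame.attrs = {}
        header = (f"# fitted_mean={fit.mean:.6g} fitted_sd={fit.sd:.6g} "
                  f"percentile_5={fit.percentile_5:.6g}\n")
        out = reports_dir / f"distribution_{scores.kind}.csv"
        out.write_text(header + frame.to_csv(index=False))

    if not config.paths.interaction_table:
        raise VinascreenError("paths.interaction_table is required")
    drug_id_map = (_load_two_column_tsv(config.validation.drug_id_map)
                   if config.validation.drug_id_map else None)
    table = validation.load_interaction_table(
        config.paths.interaction_table,
        target_column=config.validation.target_column,
        drug_column=config.validation.drug_column,
        drug_id_map=drug_id_map,
    )
    labeled = validation.label_pairs(z_selection, mm_selection, table, matrix,
                                     z_scores, mm_scores)
    thresholds = validation.known_min_thresholds(labeled)
    if thresholds is None:
        log.warning("no flagged pair is documented; novel prioritization skipped")
        novel_by_energy: list[validation.LabeledCandidate] = []
        novel_by_minmax: list[validation.LabeledCandidate] = []
    else:
        novel_by_energy, novel_by_minmax = validation.select_novel_below(labeled, thresholds)

    gene_names = (_load_two_column_tsv(config.validation.gene_names)
                  if config.validation.gene_names else None)
    drug_names = (_load_two_column_tsv(config.validation.drug_names)
                  if config.validation.drug_names else None)
    report = validation.make_report(
        labeled, z_selection, mm_selection, table, matrix, thresholds,
        novel_by_energy, novel_by_minmax, gene_names, drug_names,
    )
    report.write(reports_dir)

    manifest_digest = hashlib.sha256(
        (work_dir / "seed_manifest.tsv").read_bytes()
    ).hexdigest()
    provenance = {
        "config": config.to_dict(),
        "seed_manifest_sha256": manifest_digest,
        "counts": counts,
        "summary": report.summary,
    }
    (work_dir / "provenance.json").write_text(json.dumps(provenance, indent=1, default=str))

    return PipelineResult(
        work_dir=work_dir, matrix=matrix,
        z_scores=z_scores, mm_scores=mm_scores,
        z_selection=z_selection, mm_selection=mm_selection,
        labeled=labeled, thresholds=thresholds,
        novel_by_energy=novel_by_energy, novel_by_minmax=novel_by_minmax,
        report=report, counts=counts,
    )
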