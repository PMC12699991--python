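"""Collect per-run docking results into the receptors x ligands matrix M.

Each cell m_ij is the best (lowest, most favorable) binding energy in
kcal/mol over the pair's replicate runs, each replicate itself contributing
its best pose.  Provenance records which (replicate, seed) supplied every
minimum.  Pairs whose replicates all failed are masked missing rather than
fabricated; scoring excludes masked cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .docking import DockingJob, DockingRunResult
from .errors import VinascreenError
from .formats import Pose


def best_energy(poses: list[Pose]) -> tuple[float, int]:
    """Minimum energy over poses and the (first) pose index attaining it."""
    if not poses:
        raise VinascreenError("cannot take the best energy of zero poses")
    best = min(range(len(poses)), key=lambda k: poses[k].energy)
    return poses[best].energy, best


@dataclass
class EnergyMatrix:
    receptor_ids: list[str]
    ligand_ids: list[str]
    m: np.ndarray            # (n_receptors, n_ligands), kcal/mol, NaN = missing
    provenance: dict[tuple[str, str], tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self):
        expected = (len(self.receptor_ids), len(self.ligand_ids))
        if self.m.shape != expected:
            raise VinascreenError(f"matrix shape {self.m.shape} != {expected}")

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.m)

    def value(self, receptor_id: str, ligand_id: str) -> float:
        i = self.receptor_ids.index(receptor_id)
        j = self.ligand_ids.index(ligand_id)
        return float(self.m[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.m, index=self.receptor_ids, columns=self.ligand_ids)

    def write_tsv(self, path: str | Path, provenance_path: str | Path | None = None) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="receptor_id", float_format="%.6g")
        if provenance_path is not None:
            rows = [
                {"receptor_id": r, "ligand_id": l, "replicate": rep, "seed": seed}
                for (r, l), (rep, seed) in sorted(self.provenance.items())
            ]
            pd.DataFrame(rows, columns=["receptor_id", "ligand_id", "replicate", "seed"]).to_csv(
                provenance_path, sep="\t", index=False
            )

    @classmethod
    def read_tsv(cls, path: str | Path) -> "EnergyMatrix":
        frame = pd.read_csv(path, sep="\t", index_col="receptor_id")
        return cls(
            receptor_ids=[str(r) for r in frame.index],
            ligand_ids=[str(c) for c in frame.columns],
            m=frame.to_numpy(dtype=float),
        )


def build_matrix(
    results: dict[str, DockingRunResult],
    expected_jobs: list[DockingJob],
) -> tuple[EnergyMatrix, int]:
    """Fold run results into M; returns (matrix, masked-cell count).

    m_ij = min over the pair's surviving replicate best energies; ties
    break toward the lowest replicate index (then lowest seed) for
    provenance.  Pairs with zero surviving replicates are masked.  A whole
    missing row or column is a hard error — the campaign is unusable.
    """
    expected_keys = {j.key for j in expected_jobs}
    for key in results:
        if key not in expected_keys:
            raise VinascreenError(f"result for unknown job {key!r}")

    receptor_ids: list[str] = []
    ligand_ids: list[str] = []
    for job in expected_jobs:
        if job.receptor_id not in receptor_ids:
            receptor_ids.append(job.receptor_id)
        if job.ligand_id not in ligand_ids:
            ligand_ids.append(job.ligand_id)

    m = np.full((len(receptor_ids), len(ligand_ids)), np.nan)
    provenance: dict[tuple[str, str], tuple[int, int]] = {}
    per_pair: dict[tuple[str, str], list[tuple[float, int, int]]] = {}
    for job in expected_jobs:
        result = results.get(job.key)
        if result is None or result.status != "ok":
            continue
        energy, _ = best_energy(result.poses)
        per_pair.setdefault((job.receptor_id, job.ligand_id), []).append(
            (energy, job.replicate_index, job.seed)
        )

    masked = 0
    for i, rid in enumerate(receptor_ids):
        for j, lid in enumerate(ligand_ids):
            entries = per_pair.get((rid, lid))
            if not entries:
                masked += 1
                continue
            energy, rep, seed = min(entries)  # lexicographic: energy, replicate, seed
            m[i, j] = energy
            provenance[(rid, lid)] = (rep, seed)

    matrix = EnergyMatrix(receptor_ids=receptor_ids, ligand_ids=ligand_ids,
                          m=m, provenance=provenance)
    mask = matrix.missing_mask
    if mask.all(axis=1).any():
        bad = [receptor_ids[i] for i in np.where(mask.all(axis=1))[0]]
        raise VinascreenError(f"entire receptor row(s) missing: {bad}")
    if mask.all(axis=0).any():
        bad = [ligand_ids[j] for j in np.where(mask.all(axis=0))[0]]
        raise VinascreenError(f"entire ligand column(s) missing: {bad}")
    return matrix, masked
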