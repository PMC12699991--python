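"""Cross-validation of flagged pairs against a known drug-target table.

Flagged (receptor, ligand) pairs are labeled 1 when the pair appears in a
reference interaction table (the DrugCentral ``drug.target.interaction.tsv``
schema, via a configurable column mapping) and 0 otherwise.  The lowest raw
energy and the lowest MinMax score among the flagged known pairs then act
as evidence-backed thresholds: label-0 pairs that score strictly better
than every documented interaction are the prioritized novel candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .aggregation import EnergyMatrix
from .errors import VinascreenError
from .scoring import NormalizedScores, SelectionResult


@dataclass
class InteractionTable:
    keys: set[tuple[str, str]]              # (target accession, drug identifier), normalized
    source: str = ""
    skipped_rows: int = 0
    duplicate_rows: int = 0

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return _norm_pair(pair) in self.keys


def _norm(value: str) -> str:
    return str(value).strip().upper()


def _norm_pair(pair: tuple[str, str]) -> tuple[str, str]:
    return (_norm(pair[0]), _norm(pair[1]))


def load_interaction_table(
    path: str | Path,
    target_column: str = "ACCESSION",
    drug_column: str = "DRUG_NAME",
    drug_id_map: dict[str, str] | None = None,
) -> InteractionTable:
    """Read a headered TSV of known interactions into a normalized key set.

    ``drug_id_map`` optionally translates the drug column's values to the
    identifier space used for ligand ids (e.g. drug name -> DrugBank ID);
    unmapped values fall back to case-insensitive equality on the raw value.
    Rows missing either key are skipped and counted, duplicates deduplicated
    and counted.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    for col in (target_column, drug_column):
        if col not in frame.columns:
            raise VinascreenError(
                f"column {col!r} absent from interaction table; header is "
                f"{list(frame.columns)}"
            )
    keys: set[tuple[str, str]] = set()
    skipped = duplicates = 0
    mapping = { _norm(k): v for k, v in (drug_id_map or {}).items() }
    for target, drug in zip(frame[target_column], frame[drug_column]):
        if pd.isna(target) or pd.isna(drug) or not str(target).strip() or not str(drug).strip():
            skipped += 1
            continue
        drug = mapping.get(_norm(drug), drug)
        key = (_norm(target), _norm(drug))
        if key in keys:
            duplicates += 1
        else:
            keys.add(key)
    return InteractionTable(keys=keys, source=str(path),
                            skipped_rows=skipped, duplicate_rows=duplicates)


@dataclass
class LabeledCandidate:
    receptor_id: str
    ligand_id: str
    energy: float          # m_ij, kcal/mol
    z: float
    minmax: float
    label: int             # 1 = documented interaction, 0 = novel
    detected_by: str       # "zscore" | "minmax" | "both"


@dataclass
class PriorityThresholds:
    e_known_min: float     # lowest raw energy among flagged label-1 pairs
    mm_known_min: float    # lowest MinMax among flagged label-1 pairs


def label_pairs(
    z_selection: SelectionResult,
    mm_selection: SelectionResult,
    table: InteractionTable,
    matrix: EnergyMatrix,
    z_scores: NormalizedScores,
    mm_scores: NormalizedScores,
) -> list[LabeledCandidate]:
    """Annotate the union of the two selections with energies, both
    normalized scores, the known/novel label, and which method(s) flagged
    the pair.  Ordered by ascending raw energy."""
    union = z_selection.flagged | mm_selection.flagged
    ri = {r: i for i, r in enumerate(matrix.receptor_ids)}
    li = {l: j for j, l in enumerate(matrix.ligand_ids)}
    out: list[LabeledCandidate] = []
    for rid, lid in union:
        if rid not in ri or lid not in li:
            raise VinascreenError(f"flagged pair ({rid}, {lid}) absent from the matrix")
        i, j = ri[rid], li[lid]
        in_z = (rid, lid) in z_selection.flagged
        in_mm = (rid, lid) in mm_selection.flagged
        out.append(LabeledCandidate(
            receptor_id=rid, ligand_id=lid,
            energy=float(matrix.m[i, j]),
            z=float(z_scores.values[i, j]),
            minmax=float(mm_scores.values[i, j]),
            label=1 if (rid, lid) in table else 0,
            detected_by="both" if (in_z and in_mm) else ("zscore" if in_z else "minmax"),
        ))
    out.sort(key=lambda c: (c.energy, c.receptor_id, c.ligand_id))
    return out


def known_min_thresholds(labeled: list[LabeledCandidate]) -> PriorityThresholds | None:
    """Strongest documented interaction among the flagged pairs, on both the
    raw-energy and the MinMax scale; ``None`` (novel prioritization skipped)
    when no flagged pair is documented."""
    known = [c for c in labeled if c.label == 1]
    if not known:
        return None
    return PriorityThresholds(
        e_known_min=min(c.energy for c in known),
        mm_known_min=min(c.minmax for c in known),
    )


def select_novel_below(
    labeled: list[LabeledCandidate], thresholds: PriorityThresholds
) -> tuple[list[LabeledCandidate], list[LabeledCandidate]]:
    """Novel (label-0) pairs strictly better than every documented one.

    Returns (by raw energy, by MinMax), each sorted ascending in its own
    metric.  "Strictly": a pair exactly at the threshold is not novel-
    prioritized.
    """
    novel = [c for c in labeled if c.label == 0]
    by_energy = sorted(
        (c for c in novel if c.energy < thresholds.e_known_min),
        key=lambda c: (c.energy, c.receptor_id, c.ligand_id),
    )
    by_minmax = sorted(
        (c for c in novel if c.minmax < thresholds.mm_known_min),
        key=lambda c: (c.minmax, c.receptor_id, c.ligand_id),
    )
    return by_energy, by_minmax


def flag_rate_percent(n_flagged: int, n_known: int) -> str:
    """Known-pair flag rate as the report prints it, e.g. 21/477 -> '4.40%'."""
    if n_known == 0:
        return "n/a"
    return f"{100.0 * n_flagged / n_known:.2f}%"


@dataclass
class ReportBundle:
    candidates: pd.DataFrame          # Table-3 shape: every flagged pair
    top_known: pd.DataFrame           # Table-1 shape: best known pairs per method
    top_novel: pd.DataFrame           # Table-2 shape: best novel pairs per method
    summary: dict[str, object] = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.candidates.to_csv(out / "candidates.csv", index=False)
        self.top_known.to_csv(out / "top_known.csv", index=False)
        self.top_novel.to_csv(out / "top_novel.csv", index=False)
        lines = [f"{k}\t{v}" for k, v in self.summary.items()]
        (out / "summary.tsv").write_text("\n".join(lines) + "\n")


def make_report(
    labeled: list[LabeledCandidate],
    z_selection: SelectionResult,
    mm_selection: SelectionResult,
    table: InteractionTable,
    matrix: EnergyMatrix,
    thresholds: PriorityThresholds | None,
    novel_by_energy: list[LabeledCandidate] | None,
    novel_by_minmax: list[LabeledCandidate] | None,
    gene_names: dict[str, str] | None = None,
    drug_names: dict[str, str] | None = None,
    top_n: int = 3,
) -> ReportBundle:
    """Assemble the candidate tables and the summary counts."""
    gene_names = gene_names or {}
    drug_names = drug_names or {}

    def rows(cands: list[LabeledCandidate]) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "target_id": c.receptor_id,
                    "gene": gene_names.get(c.receptor_id, ""),
                    "drug_id": c.ligand_id,
                    "drug_name": drug_names.get(c.ligand_id, ""),
                    "energy_kcal_mol": c.energy,
                    "zscore": c.z,
                    "minmax": c.minmax,
                    "label": c.label,
                    "detected_by": c.detected_by,
                }
                for c in cands
            ],
            columns=["target_id", "gene", "drug_id", "drug_name", "energy_kcal_mol",
                     "zscore", "minmax", "label", "detected_by"],
        )

    known = [c for c in labeled if c.label == 1]
    known_by_z = sorted(known, key=lambda c: c.z)[:top_n]
    known_by_mm = sorted(known, key=lambda c: c.minmax)[:top_n]
    novel = [c for c in labeled if c.label == 0]
    novel_by_z = sorted(novel, key=lambda c: c.z)[:top_n]
    novel_by_mm = sorted(novel, key=lambda c: c.minmax)[:top_n]

    top_known = rows(known_by_z).assign(ranked_by="zscore")
    top_known = pd.concat([top_known, rows(known_by_mm).assign(ranked_by="minmax")],
                          ignore_index=True)
    top_novel = rows(novel_by_z).assign(ranked_by="zscore")
    top_novel = pd.concat([top_novel, rows(novel_by_mm).assign(ranked_by="minmax")],
                          ignore_index=True)

    n_pairs = int(matrix.m.size)
    matrix_pairs = {
        (r, l) for r in matrix.receptor_ids for l in matrix.ligand_ids
    }
    known_in_matrix = {p for p in matrix_pairs if p in table}
    known_flagged_z = [c for c in known if c.detected_by in ("zscore", "both")]
    known_flagged_mm = [c for c in known if c.detected_by in ("minmax", "both")]
    both = sum(1 for c in labeled if c.detected_by == "both")

    summary: dict[str, object] = {
        "total_pairs": n_pairs,
        "known_pairs_in_matrix": len(known_in_matrix),
        "flagged_zscore": len(z_selection.flagged),
        "flagged_minmax": len(mm_selection.flagged),
        "flagged_union": len(labeled),
        "flagged_both": both,
        "known_flagged_zscore": len(known_flagged_z),
        "known_flagged_minmax": len(known_flagged_mm),
        "known_flag_rate_zscore": flag_rate_percent(len(known_flagged_z), len(known_in_matrix)),
        "known_flag_rate_minmax": flag_rate_percent(len(known_flagged_mm), len(known_in_matrix)),
    }
    if thresholds is not None:
        summary["energy_threshold_kcal_mol"] = f"{thresholds.e_known_min:.3f}"
        summary["minmax_threshold"] = f"{thresholds.mm_known_min:.3f}"
        summary["novel_below_energy_threshold"] = len(novel_by_energy or [])
        summary["novel_below_minmax_threshold"] = len(novel_by_minmax or [])
    else:
        summary["energy_threshold_kcal_mol"] = "n/a"
        summary["minmax_threshold"] = "n/a"

    return ReportBundle(candidates=rows(labeled), top_known=top_known,
                        top_novel=top_novel, summary=summary)
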