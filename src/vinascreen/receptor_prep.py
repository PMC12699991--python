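"""Receptor preparation for blind docking.

AlphaFold models store the per-residue pLDDT confidence (0-100) in the PDB
temperature-factor column.  Residues below the confidence threshold (70 by
default) are removed before docking so that disordered or poorly predicted
regions do not present spurious binding surfaces.  The search box for blind
docking is then the axis-aligned bounding box of the trimmed structure plus
a margin, so the docking engine scans the whole receptor surface.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import EmptyInputError, InconsistentConfidenceError, VinascreenError
from .formats import Molecule, ReceptorStructure, perceive_bonds

DEFAULT_PLDDT_THRESHOLD = 70.0
DEFAULT_BOX_MARGIN = 10.0  # Angstrom


@dataclass(frozen=True)
class SearchBox:
    """Axis-aligned docking search volume (Vina center/size convention, Å)."""

    center_x: float
    center_y: float
    center_z: float
    size_x: float
    size_y: float
    size_z: float

    def __post_init__(self):
        if min(self.size_x, self.size_y, self.size_z) <= 0:
            raise ValueError("box sizes must be positive")

    def contains(self, x: float, y: float, z: float, eps: float = 1e-9) -> bool:
        return (
            abs(x - self.center_x) <= self.size_x / 2 + eps
            and abs(y - self.center_y) <= self.size_y / 2 + eps
            and abs(z - self.center_z) <= self.size_z / 2 + eps
        )

    def to_key_value(self) -> str:
        """Plain ``key=value`` serialization consumed by config generation."""
        return "".join(
            f"{k}={getattr(self, k):.3f}\n"
            for k in ("center_x", "center_y", "center_z", "size_x", "size_y", "size_z")
        )

    @classmethod
    def from_key_value(cls, text: str) -> "SearchBox":
        vals = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            vals[key.strip()] = float(value)
        return cls(**vals)


@dataclass
class TrimReport:
    """Per-chain kept/removed residue counts from a pLDDT trim."""

    threshold: float
    kept: dict[str, int]
    removed: dict[str, int]

    @property
    def total_kept(self) -> int:
        return sum(self.kept.values())

    @property
    def total_removed(self) -> int:
        return sum(self.removed.values())


def residue_plddt(residue) -> float:
    """pLDDT of a residue, checking the AlphaFold one-value-per-residue
    convention; mixed values within a residue indicate a corrupted or
    non-AlphaFold file."""
    values = {a.plddt_or_bfactor for a in residue.atoms}
    if len(values) > 1:
        raise InconsistentConfidenceError(
            f"residue {residue.chain}/{residue.number} {residue.name} carries "
            f"{len(values)} distinct pLDDT values"
        )
    return residue.atoms[0].plddt_or_bfactor


def filter_by_plddt(
    structure: ReceptorStructure,
    threshold: float = DEFAULT_PLDDT_THRESHOLD,
) -> tuple[ReceptorStructure, TrimReport]:
    """Remove residues whose pLDDT is below ``threshold``.

    Residues exactly at the threshold are kept ("below 70" read strictly).
    Original residue order and numbering are preserved; chains may end up
    split into fragments and no capping is attempted (the receptor is rigid,
    only atom positions matter downstream).

    Refuses to run on structures not declared AlphaFold-sourced, so crystal
    structures are never silently trimmed by B-factor.
    """
    if not structure.alphafold_sourced:
        raise VinascreenError(
            "structure is not tagged AlphaFold-sourced; temperature factors are "
            "B-factors, refusing pLDDT filtering"
        )
    kept: dict[str, int] = {}
    removed: dict[str, int] = {}
    surviving = []
    for res in structure.residues:
        if residue_plddt(res) >= threshold:
            surviving.append(res)
            kept[res.chain] = kept.get(res.chain, 0) + 1
        else:
            removed[res.chain] = removed.get(res.chain, 0) + 1
    trimmed = ReceptorStructure(
        receptor_id=structure.receptor_id,
        residues=surviving,
        alphafold_sourced=True,
    )
    return trimmed, TrimReport(threshold=threshold, kept=kept, removed=removed)


def compute_search_box(structure: ReceptorStructure, margin: float = DEFAULT_BOX_MARGIN) -> SearchBox:
    """Bounding box of all receptor atoms, extended by ``margin`` per face.

    center = midpoint of the per-axis extrema; size = extent + 2*margin.
    """
    atoms = structure.atoms
    if not atoms:
        raise EmptyInputError("cannot box an empty structure")
    if margin < 0:
        raise ValueError("margin must be non-negative")
    xs = [a.x for a in atoms]
    ys = [a.y for a in atoms]
    zs = [a.z for a in atoms]
    center = [(max(v) + min(v)) / 2 for v in (xs, ys, zs)]
    size = [max(v) - min(v) + 2 * margin for v in (xs, ys, zs)]
    return SearchBox(center[0], center[1], center[2], size[0], size[1], size[2])


def prepare_receptor(
    structure: ReceptorStructure,
    plddt_threshold: float = DEFAULT_PLDDT_THRESHOLD,
    box_margin: float = DEFAULT_BOX_MARGIN,
) -> tuple[ReceptorStructure, SearchBox, TrimReport]:
    """Trim, charge, type and box a receptor for rigid blind docking.

    Partial charges use the same PEOE assigner as ligands (the original
    workflow's converter assigns charges without naming the model; PEOE is
    this package's documented default) and atom types use the minimal
    AutoDock typing rules.  Bonds are perceived from distances since PDB
    receptor files carry no connectivity.
    """
    from .ligand_prep import assign_autodock_types, assign_gasteiger_charges

    trimmed, report = filter_by_plddt(structure, threshold=plddt_threshold)
    if not trimmed.residues:
        raise EmptyInputError(
            f"receptor {structure.receptor_id!r}: no residue reaches pLDDT {plddt_threshold}"
        )
    atoms = trimmed.atoms
    mol = Molecule(atoms=atoms, bonds=perceive_bonds(atoms), name=trimmed.receptor_id)
    assign_gasteiger_charges(mol)
    assign_autodock_types(mol)
    box = compute_search_box(trimmed, margin=box_margin)
    return trimmed, box, report
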