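"""Synthetic inputs with planted ground truth.

Every pipeline stage is testable offline: receptors as schematic extended
backbones with controlled per-residue pLDDT, small organic ligands from
topological templates, a deterministic mock energy landscape with planted
high-affinity pairs, and decoy interaction tables.  Geometry is schematic —
valid formats and plausible distances, no energy physics — and every
generator is a pure function of its seed and spec, returning the ground
truth alongside the artifact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import VinascreenError
from .formats import AROMATIC, Atom, Bond, Molecule, write_sdf_v2000
from .rng import stable_seed

# ---------------------------------------------------------------------------
# Receptor fixtures
# ---------------------------------------------------------------------------

_BACKBONE = (  # name, element, offset from residue origin (Å)
    ("N", "N", (0.0, 0.0, 0.0)),
    ("CA", "C", (1.46, 0.0, 0.0)),
    ("C", "C", (2.2, 1.3, 0.0)),
    ("O", "O", (1.7, 2.4, 0.0)),
)


def generate_receptor_fixture(
    n_residues: int,
    fraction_below: float = 0.4,
    seed: int = 0,
    receptor_id: str = "RCPT",
    low_range: tuple[float, float] = (40.0, 69.5),
    high_range: tuple[float, float] = (70.0, 98.0),
) -> tuple[str, int]:
    """A synthetic AlphaFold-style PDB and its ground-truth trim count.

    Exactly ``round(fraction_below * n_residues)`` residues receive a pLDDT
    drawn from ``low_range`` (below the 70 cutoff); the rest from
    ``high_range``.  Geometry is an extended backbone trace (3.8 Å spacing,
    gentle zig-zag), carrying no physical realism.
    """
    if n_residues < 1:
        raise VinascreenError("n_residues must be >= 1")
    if not 0 <= fraction_below <= 1:
        raise VinascreenError(f"fraction_below must lie in [0, 1], got {fraction_below}")
    rng = np.random.default_rng(stable_seed("receptor", seed, receptor_id))
    n_low = int(round(fraction_below * n_residues))
    low_idx = set(rng.choice(n_residues, size=n_low, replace=False).tolist())
    lines = []
    serial = 0
    for res_i in range(n_residues):
        if res_i in low_idx:
            plddt = rng.uniform(*low_range)
        else:
            plddt = rng.uniform(*high_range)
        base = (res_i * 3.8, 1.5 * (res_i % 2), 0.3 * math.sin(res_i))
        for name, element, offset in _BACKBONE:
            serial += 1
            x, y, z = (b + o for b, o in zip(base, offset))
            pad_name = f" {name:<3s}"
            lines.append(
                f"ATOM  {serial:>5d} {pad_name}{' '}ALA A{res_i + 1:>4d} "
                f"   {x:>8.3f}{y:>8.3f}{z:>8.3f}{1.00:>6.2f}{plddt:>6.2f}"
                f"          {element:>2s}"
            )
    lines.append("END")
    return "\n".join(lines) + "\n", n_low


# ---------------------------------------------------------------------------
# Ligand fixtures
# ---------------------------------------------------------------------------

_CC = 1.54   # sp3 C-C bond length, Å
_CH = 1.09
_CAR = 1.39  # aromatic C-C


def _jitter(rng: np.random.Generator) -> np.ndarray:
    return rng.uniform(-0.01, 0.01, size=3)


def _chain_molecule(n_carbons: int, rng: np.random.Generator, name: str) -> Molecule:
    """Zig-zag alkane chain with explicit hydrogens."""
    atoms: list[Atom] = []
    bonds: list[Bond] = []
    angle = math.radians(109.5 / 2)
    positions = []
    for k in range(n_carbons):
        positions.append(np.array([
            k * _CC * math.sin(angle),
            _CC * math.cos(angle) * (k % 2),
            0.0,
        ]))
    for k, pos in enumerate(positions):
        pos = pos + _jitter(rng)
        atoms.append(Atom(serial=k + 1, name=f"C{k + 1}", residue_name="LIG", chain="A",
                          residue_number=1, x=pos[0], y=pos[1], z=pos[2], element="C"))
        if k:
            bonds.append(Bond(k - 1, k, 1))
    # hydrogens to fill valence 4
    h_count = 0
    for k in range(n_carbons):
        n_heavy = (1 if k > 0 else 0) + (1 if k < n_carbons - 1 else 0)
        for h in range(4 - n_heavy):
            h_count += 1
            direction = np.array([
                0.3 * math.cos(2.1 * h + k), 0.9 * (-1) ** (h + k), 0.6 * math.sin(2.1 * h + k),
            ])
            direction /= np.linalg.norm(direction)
            pos = np.array(atoms[k].coords) + _CH * direction + _jitter(rng)
            atoms.append(Atom(serial=n_carbons + h_count, name=f"H{h_count}",
                              residue_name="LIG", chain="A", residue_number=1,
                              x=pos[0], y=pos[1], z=pos[2], element="H"))
            bonds.append(Bond(k, len(atoms) - 1, 1))
    return Molecule(atoms=atoms, bonds=bonds, name=name)


def _ring_molecule(rng: np.random.Generator, name: str) -> Molecule:
    """Benzene: six aromatic carbons, six radial hydrogens."""
    atoms: list[Atom] = []
    bonds: list[Bond] = []
    r_c = _CAR / (2 * math.sin(math.pi / 6))
    for k in range(6):
        theta = 2 * math.pi * k / 6
        pos = np.array([r_c * math.cos(theta), r_c * math.sin(theta), 0.0]) + _jitter(rng)
        atoms.append(Atom(serial=k + 1, name=f"C{k + 1}", residue_name="LIG", chain="A",
                          residue_number=1, x=pos[0], y=pos[1], z=pos[2], element="C"))
        bonds.append(Bond(k, (k + 1) % 6, AROMATIC))
    for k in range(6):
        theta = 2 * math.pi * k / 6
        pos = np.array([(r_c + _CH) * math.cos(theta), (r_c + _CH) * math.sin(theta), 0.0])
        pos = pos + _jitter(rng)
        atoms.append(Atom(serial=7 + k, name=f"H{k + 1}", residue_name="LIG", chain="A",
                          residue_number=1, x=pos[0], y=pos[1], z=pos[2], element="H"))
        bonds.append(Bond(k, 6 + k, 1))
    return Molecule(atoms=atoms, bonds=bonds, name=name)


def _branched_molecule(rng: np.random.Generator, name: str) -> Molecule:
    """2-methylbutane: one rotatable bond (C2-C3) under the AutoDock rules."""
    mol = _chain_molecule(4, rng, name)
    # graft a methyl on C2 (index 1)
    pos = np.array(mol.atoms[1].coords) + np.array([0.0, -1.2, 0.95]) + _jitter(rng)
    atoms = list(mol.atoms)
    bonds = list(mol.bonds)
    # drop one H of C2 to make room
    drop = next(i for i, a in enumerate(atoms)
                if a.element == "H" and 1 in (b.i for b in bonds if b.j == i))
    atoms.pop(drop)
    bonds = [Bond(b.i - (b.i > drop), b.j - (b.j > drop), b.order)
             for b in bonds if drop not in (b.i, b.j)]
    c5 = len(atoms)
    atoms.append(Atom(serial=c5 + 1, name="C5", residue_name="LIG", chain="A",
                      residue_number=1, x=pos[0], y=pos[1], z=pos[2], element="C"))
    bonds.append(Bond(1, c5, 1))
    for h in range(3):
        hpos = pos + np.array([0.9 * math.cos(2.1 * h), -0.7, 0.9 * math.sin(2.1 * h)])
        hpos = hpos + _jitter(rng)
        atoms.append(Atom(serial=len(atoms) + 1, name=f"H9{h}", residue_name="LIG",
                          chain="A", residue_number=1, x=hpos[0], y=hpos[1], z=hpos[2],
                          element="H"))
        bonds.append(Bond(c5, len(atoms) - 1, 1))
    return Molecule(atoms=atoms, bonds=bonds, name=name)


def generate_ligand_fixture(template: str, seed: int = 0, name: str = "") -> tuple[str, int]:
    """A V2000 SDF for a topological template plus its ground-truth
    rotatable-bond count (AutoDock rules applied to the template by hand).

    Templates: ``rigid-ring`` (benzene, 0), ``chain-N`` (N-carbon alkane,
    max(N-3, 0)), ``branched`` (2-methylbutane, 1).
    """
    rng = np.random.default_rng(stable_seed("ligand", seed, template))
    if template == "rigid-ring":
        mol = _ring_molecule(rng, name or "benzene")
        expected = 0
    elif template.startswith("chain-"):
        try:
            n = int(template.split("-", 1)[1])
        except ValueError:
            raise VinascreenError(f"unknown template {template!r}") from None
        if n < 1:
            raise VinascreenError(f"chain length must be >= 1 in {template!r}")
        mol = _chain_molecule(n, rng, name or f"alkane{n}")
        expected = max(n - 3, 0)
    elif template == "branched":
        mol = _branched_molecule(rng, name or "isopentane")
        expected = 1
    else:
        raise VinascreenError(f"unknown template {template!r}")
    return write_sdf_v2000(mol), expected


# ---------------------------------------------------------------------------
# Mock energy landscape
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedPair:
    shift: float   # kcal/mol added to the receptor's base mean
    tag: str       # "known" | "novel"


@dataclass
class MockLandscape:
    """A stated world of docking energies.

    Unplanted pairs draw their best energy from the receptor's base normal
    distribution (one draw per pair, seed-stable); planted pairs sit exactly
    at ``receptor mean + shift`` so the planted affinity is exact ground
    truth.  On top of either, each replicate adds independent normal noise
    (sd ``replicate_noise_sd``), which is the only randomness separating
    replicates.
    """

    receptor_ids: list[str]
    ligand_ids: list[str]
    base_mean: dict[str, float]
    base_sd: dict[str, float]
    planted: dict[tuple[str, str], PlantedPair] = field(default_factory=dict)
    replicate_noise_sd: float = 0.2
    master_seed: int = 0

    def __post_init__(self):
        if self.replicate_noise_sd < 0:
            raise VinascreenError("replicate noise sd must be >= 0")
        for rid, lid in self.planted:
            if rid not in self.receptor_ids or lid not in self.ligand_ids:
                raise VinascreenError(f"planted pair ({rid}, {lid}) references unknown ids")

    def base_energy(self, receptor_id: str, ligand_id: str) -> float:
        if receptor_id not in self.base_mean:
            raise VinascreenError(f"receptor {receptor_id!r} outside landscape")
        if ligand_id not in self.ligand_ids:
            raise VinascreenError(f"ligand {ligand_id!r} outside landscape")
        pair = self.planted.get((receptor_id, ligand_id))
        if pair is not None:
            return self.base_mean[receptor_id] + pair.shift
        rng = np.random.default_rng(
            stable_seed("base", self.master_seed, receptor_id, ligand_id)
        )
        return float(rng.normal(self.base_mean[receptor_id], self.base_sd[receptor_id]))

    def pose_energies(
        self, receptor_id: str, ligand_id: str, replicate_seed: int, n_modes: int = 9
    ) -> list[float]:
        """Best-first pose energies for one replicate run."""
        base = self.base_energy(receptor_id, ligand_id)
        rng = np.random.default_rng(
            stable_seed("rep", self.master_seed, receptor_id, ligand_id, replicate_seed)
        )
        best = base + float(rng.normal(0.0, self.replicate_noise_sd))
        gaps = np.abs(rng.normal(0.4, 0.2, size=max(n_modes - 1, 0)))
        return [best] + list(best + np.cumsum(gaps))

    def planted_known(self) -> list[tuple[str, str]]:
        return sorted(k for k, v in self.planted.items() if v.tag == "known")

    def planted_novel(self) -> list[tuple[str, str]]:
        return sorted(k for k, v in self.planted.items() if v.tag == "novel")

    def to_json(self) -> str:
        import json

        return json.dumps({
            "receptor_ids": self.receptor_ids,
            "ligand_ids": self.ligand_ids,
            "base_mean": self.base_mean,
            "base_sd": self.base_sd,
            "planted": [
                {"receptor_id": r, "ligand_id": l, "shift": p.shift, "tag": p.tag}
                for (r, l), p in sorted(self.planted.items())
            ],
            "replicate_noise_sd": self.replicate_noise_sd,
            "master_seed": self.master_seed,
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "MockLandscape":
        import json

        data = json.loads(text)
        return cls(
            receptor_ids=data["receptor_ids"],
            ligand_ids=data["ligand_ids"],
            base_mean=data["base_mean"],
            base_sd=data["base_sd"],
            planted={
                (p["receptor_id"], p["ligand_id"]): PlantedPair(p["shift"], p["tag"])
                for p in data["planted"]
            },
            replicate_noise_sd=data["replicate_noise_sd"],
            master_seed=data["master_seed"],
        )


def make_landscape(
    n_receptors: int = 20,
    n_ligands: int = 500,
    base_mean: float = -7.0,
    base_sd: float = 1.0,
    n_known: int = 10,
    known_shift: float = -5.0,
    n_novel: int = 5,
    novel_shift: float = -7.0,
    replicate_noise_sd: float = 0.2,
    master_seed: int = 0,
) -> MockLandscape:
    """The default stated world: homogeneous N(base_mean, base_sd) rows with
    planted known pairs (moderately strong binders that a reference database
    would document) and planted novel pairs (stronger still)."""
    receptor_ids = [f"R{k:03d}" for k in range(1, n_receptors + 1)]
    ligand_ids = [f"L{k:04d}" for k in range(1, n_ligands + 1)]
    rng = np.random.default_rng(stable_seed("plant", master_seed))
    n_pairs = n_receptors * n_ligands
    if n_known + n_novel > n_pairs:
        raise VinascreenError("more planted pairs than matrix cells")
    flat = rng.choice(n_pairs, size=n_known + n_novel, replace=False)
    planted: dict[tuple[str, str], PlantedPair] = {}
    for rank, idx in enumerate(flat):
        rid = receptor_ids[idx // n_ligands]
        lid = ligand_ids[idx % n_ligands]
        if rank < n_known:
            planted[(rid, lid)] = PlantedPair(shift=known_shift, tag="known")
        else:
            planted[(rid, lid)] = PlantedPair(shift=novel_shift, tag="novel")
    return MockLandscape(
        receptor_ids=receptor_ids,
        ligand_ids=ligand_ids,
        base_mean={r: base_mean for r in receptor_ids},
        base_sd={r: base_sd for r in receptor_ids},
        planted=planted,
        replicate_noise_sd=replicate_noise_sd,
        master_seed=master_seed,
    )


def generate_interaction_fixture(
    landscape: MockLandscape,
    extra_decoys: int = 20,
    seed: int = 0,
    target_column: str = "ACCESSION",
    drug_column: str = "DRUG_NAME",
) -> str:
    """A decoy known-interaction TSV: every planted known pair plus
    ``extra_decoys`` random unplanted pairs (decoys never coincide with any
    planted pair)."""
    known = landscape.planted_known()
    if not known:
        raise VinascreenError("landscape has no planted known pairs")
    rng = np.random.default_rng(stable_seed("decoys", seed))
    n_pairs = len(landscape.receptor_ids) * len(landscape.ligand_ids)
    forbidden = set(landscape.planted)
    decoys: list[tuple[str, str]] = []
    attempts = 0
    while len(decoys) < extra_decoys:
        attempts += 1
        if attempts > 1000 * (extra_decoys + 1):
            raise VinascreenError("cannot place decoys without colliding with planted pairs")
        idx = int(rng.integers(n_pairs))
        rid = landscape.receptor_ids[idx // len(landscape.ligand_ids)]
        lid = landscape.ligand_ids[idx % len(landscape.ligand_ids)]
        if (rid, lid) in forbidden or (rid, lid) in decoys:
            continue
        decoys.append((rid, lid))
    lines = [f"{target_column}\t{drug_column}"]
    for rid, lid in known + decoys:
        lines.append(f"{rid}\t{lid}")
    return "\n".join(lines) + "\n"
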