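"""Ligand preparation: partial charges, rotatable bonds, torsion tree.

Charges follow the iterative partial equalization of orbital
electronegativities (PEOE) scheme: each atom's electronegativity is a
quadratic in its current charge, chi(q) = a + b*q + c*q**2, with (a, b, c)
tabulated per element and hybridization; at iteration k, charge flows
across every bond from the less to the more electronegative atom in
proportion to the electronegativity difference, scaled by the donor's
cation electronegativity and damped by (1/2)**k.  Six iterations are the
published default and leave residual transfers below ~1e-2 e.

Rotatable-bond detection and the rigid-fragment torsion tree follow the
AutoDock conventions, so the resulting PDBQT encodes exactly the torsional
degrees of freedom the docking engine is allowed to sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .errors import UnsupportedElementError, VinascreenError
from .formats import AROMATIC, Bond, Molecule

# PEOE coefficients (a, b, c) per (element, hybridization); chi in eV.
# Hydrogen has a single entry and the special cation electronegativity 20.02
# used as the damping denominator when it is the donor.
PEOE_PARAMETERS: dict[tuple[str, str], tuple[float, float, float]] = {
    ("H", "*"): (7.17, 6.24, -0.56),
    ("C", "sp3"): (7.98, 9.18, 1.88),
    ("C", "sp2"): (8.79, 9.32, 1.51),
    ("C", "sp"): (10.39, 9.45, 0.73),
    ("N", "sp3"): (11.54, 10.82, 1.36),
    ("N", "sp2"): (12.87, 11.15, 0.85),
    ("N", "sp"): (15.68, 11.70, -0.27),
    ("O", "sp3"): (14.18, 12.92, 1.39),
    ("O", "sp2"): (17.07, 13.79, 0.47),
    ("F", "*"): (14.66, 13.85, 2.31),
    ("Cl", "*"): (11.00, 9.69, 1.35),
    ("Br", "*"): (10.08, 8.47, 1.16),
    ("I", "*"): (9.90, 7.96, 0.96),
    ("S", "*"): (10.14, 9.13, 1.38),
    ("P", "*"): (8.90, 8.24, 0.96),
}

HYDROGEN_CATION_CHI = 20.02
DEFAULT_PEOE_ITERATIONS = 6


@dataclass
class TorsionTree:
    """Rigid fragments (atom-index tuples) linked by rotatable bonds.

    ``children[node]`` lists ``(child_node, (parent_atom, child_atom))``
    pairs, where the atom pair is the rotatable bond crossing from the
    parent fragment into the child fragment.
    """

    fragments: list[tuple[int, ...]]
    children: dict[int, list[tuple[int, tuple[int, int]]]] = field(default_factory=dict)


@dataclass
class LigandMolecule:
    """A molecule annotated with everything ligand PDBQT output needs."""

    ligand_id: str
    molecule: Molecule
    rotatable_bonds: list[Bond] = field(default_factory=list)
    torsion_root: int | None = None
    torsion_tree: TorsionTree | None = None

    @property
    def charges(self) -> list[float | None]:
        return [a.partial_charge for a in self.molecule.atoms]


# ---------------------------------------------------------------------------
# Hybridization and aromaticity
# ---------------------------------------------------------------------------

def infer_hybridizations(molecule: Molecule) -> list[str]:
    """sp/sp2/sp3 per atom from bond orders: a triple bond or two doubles
    make sp; any double or aromatic bond makes sp2; otherwise sp3."""
    hyb = []
    order_of: dict[int, list[int | str]] = {i: [] for i in range(len(molecule.atoms))}
    for b in molecule.bonds:
        order_of[b.i].append(b.order)
        order_of[b.j].append(b.order)
    for i in range(len(molecule.atoms)):
        orders = order_of[i]
        n_double = sum(1 for o in orders if o == 2)
        if 3 in orders or n_double >= 2:
            hyb.append("sp")
        elif n_double or AROMATIC in orders:
            hyb.append("sp2")
        else:
            hyb.append("sp3")
    return hyb


def mark_aromatic_rings(molecule: Molecule, planarity_tol: float = 0.15) -> Molecule:
    """Heuristic aromaticity for order-less (PDB-derived) molecules.

    Marks the bonds of six-membered rings aromatic when every ring atom is
    carbon or nitrogen with at most three neighbors and the ring is planar
    within ``planarity_tol`` Å.  Molecules that already carry double or
    aromatic bond orders (SDF input) are returned unchanged.
    """
    if any(b.order != 1 for b in molecule.bonds):
        return molecule
    import numpy as np

    graph = _bond_graph(molecule)
    aromatic_pairs: set[tuple[int, int]] = set()
    for ring in nx.cycle_basis(graph):
        if len(ring) != 6:
            continue
        if not all(
            molecule.atoms[i].element in ("C", "N") and graph.degree(i) <= 3
            for i in ring
        ):
            continue
        coords = np.array([molecule.atoms[i].coords for i in ring])
        centered = coords - coords.mean(axis=0)
        # distance to best-fit plane = projections on smallest singular axis
        _, _, vt = np.linalg.svd(centered)
        if np.abs(centered @ vt[-1]).max() > planarity_tol:
            continue
        for k in range(6):
            a, b = ring[k], ring[(k + 1) % 6]
            aromatic_pairs.add((min(a, b), max(a, b)))
    if not aromatic_pairs:
        return molecule
    new_bonds = [
        Bond(b.i, b.j, AROMATIC) if b.key in aromatic_pairs else b
        for b in molecule.bonds
    ]
    return Molecule(atoms=molecule.atoms, bonds=new_bonds,
                    formal_charge=molecule.formal_charge, name=molecule.name)


def _bond_graph(molecule: Molecule) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(len(molecule.atoms)))
    g.add_edges_from((b.i, b.j) for b in molecule.bonds)
    return g


# ---------------------------------------------------------------------------
# Gasteiger (PEOE) charges
# ---------------------------------------------------------------------------

def _peoe_params(molecule: Molecule) -> list[tuple[float, float, float]]:
    hyb = infer_hybridizations(molecule)
    params = []
    for atom, h in zip(molecule.atoms, hyb):
        key = (atom.element, "*") if (atom.element, "*") in PEOE_PARAMETERS else (atom.element, h)
        if key not in PEOE_PARAMETERS:
            raise UnsupportedElementError(
                f"no PEOE parameters for atom {atom.name!r} "
                f"(element {atom.element}, hybridization {h})"
            )
        params.append(PEOE_PARAMETERS[key])
    return params


def assign_gasteiger_charges(
    molecule: Molecule, iterations: int = DEFAULT_PEOE_ITERATIONS
) -> list[float]:
    """Iterative PEOE partial charges; writes them onto the atoms and
    returns the per-atom list.  Total charge is conserved exactly (each
    transfer is antisymmetric), so the sum equals the formal charge."""
    params = _peoe_params(molecule)
    n = len(molecule.atoms)
    charges = [0.0] * n
    if molecule.formal_charge and n:
        # seed the net charge uniformly; equalization redistributes it
        charges = [molecule.formal_charge / n] * n
    damp = 1.0
    for _ in range(iterations):
        damp *= 0.5
        chi = [a + b * q + c * q * q for (a, b, c), q in zip(params, charges)]
        delta = [0.0] * n
        for bond in molecule.bonds:
            ci, cj = chi[bond.i], chi[bond.j]
            if ci == cj:
                continue
            donor, acceptor = (bond.i, bond.j) if ci < cj else (bond.j, bond.i)
            if molecule.atoms[donor].element == "H":
                denom = HYDROGEN_CATION_CHI
            else:
                denom = sum(params[donor])
            dq = abs(cj - ci) / denom * damp
            delta[donor] += dq
            delta[acceptor] -= dq
        charges = [q + d for q, d in zip(charges, delta)]
    for atom, q in zip(molecule.atoms, charges):
        atom.partial_charge = q
    return charges


# ---------------------------------------------------------------------------
# Rotatable bonds and torsion tree
# ---------------------------------------------------------------------------

def _ring_bonds(molecule: Molecule) -> set[tuple[int, int]]:
    graph = _bond_graph(molecule)
    in_ring: set[tuple[int, int]] = set()
    for ring in nx.cycle_basis(graph):
        m = len(ring)
        for k in range(m):
            a, b = ring[k], ring[(k + 1) % m]
            in_ring.add((min(a, b), max(a, b)))
    return in_ring


def _is_amide_cn(molecule: Molecule, bond: Bond) -> bool:
    """C-N single bond where the carbon also carries a double bond to O."""
    ai = molecule.atoms[bond.i].element
    aj = molecule.atoms[bond.j].element
    if {ai, aj} != {"C", "N"}:
        return False
    carbon = bond.i if ai == "C" else bond.j
    for other in molecule.bonds:
        if other.order != 2:
            continue
        if carbon not in (other.i, other.j):
            continue
        partner = other.j if other.i == carbon else other.i
        if molecule.atoms[partner].element == "O":
            return True
    return False


def find_rotatable_bonds(molecule: Molecule, exclude_amides: bool = True) -> list[Bond]:
    """Bonds the docking engine may rotate: single order, acyclic, both
    endpoints bonded to at least one other heavy atom, and (by AutoDock
    convention, configurable) not an amide C-N."""
    ring = _ring_bonds(molecule)
    heavy_neighbors = [0] * len(molecule.atoms)
    for b in molecule.bonds:
        if molecule.atoms[b.j].element != "H":
            heavy_neighbors[b.i] += 1
        if molecule.atoms[b.i].element != "H":
            heavy_neighbors[b.j] += 1
    rotatable = []
    for b in molecule.bonds:
        if b.order != 1 or b.key in ring:
            continue
        if molecule.atoms[b.i].element == "H" or molecule.atoms[b.j].element == "H":
            continue
        # non-terminal: each endpoint has a heavy neighbor besides the other
        if heavy_neighbors[b.i] < 2 or heavy_neighbors[b.j] < 2:
            continue
        if exclude_amides and _is_amide_cn(molecule, b):
            continue
        rotatable.append(b)
    return rotatable


def build_torsion_tree(
    molecule: Molecule, rotatable: list[Bond]
) -> tuple[int, TorsionTree]:
    """Contract rigid fragments into nodes and root the tree.

    Fragments are the connected components after deleting the rotatable
    bonds.  The root is the fragment minimizing the size (in atoms) of its
    largest branch; ties break toward the fragment containing the lowest
    atom index.  Rotatable bonds inside rings are a precondition leak and
    rejected.
    """
    ring = _ring_bonds(molecule)
    bond_keys = {b.key for b in molecule.bonds}
    for b in rotatable:
        if b.key not in bond_keys:
            raise VinascreenError(f"rotatable bond {b.key} is not a molecule bond")
        if b.key in ring:
            raise VinascreenError(f"rotatable bond {b.key} lies in a ring")

    graph = _bond_graph(molecule)
    rot_keys = {b.key for b in rotatable}
    cut = graph.copy()
    cut.remove_edges_from(rot_keys)
    fragments = [tuple(sorted(c)) for c in nx.connected_components(cut)]
    fragments.sort(key=lambda f: f[0])
    frag_of = {a: fi for fi, frag in enumerate(fragments) for a in frag}

    # fragment-level tree: nodes = fragments, edges = rotatable bonds
    ftree = nx.Graph()
    ftree.add_nodes_from(range(len(fragments)))
    edge_atoms: dict[tuple[int, int], tuple[int, int]] = {}
    for a, b in rot_keys:
        fa, fb = frag_of[a], frag_of[b]
        ftree.add_edge(fa, fb)
        edge_atoms[(fa, fb)] = (a, b)
        edge_atoms[(fb, fa)] = (b, a)

    def largest_branch(root: int) -> int:
        sizes = []
        for nb in ftree.neighbors(root):
            seen = {root}
            stack = [nb]
            atoms = 0
            while stack:
                node = stack.pop()
                if node in seen:
                    continue
                seen.add(node)
                atoms += len(fragments[node])
                stack.extend(ftree.neighbors(node))
            sizes.append(atoms)
        return max(sizes, default=0)

    root = min(range(len(fragments)), key=lambda fi: (largest_branch(fi), fragments[fi][0]))

    children: dict[int, list[tuple[int, tuple[int, int]]]] = {}
    for parent, child in nx.bfs_edges(ftree, root):
        children.setdefault(parent, []).append((child, edge_atoms[(parent, child)]))
    for lst in children.values():
        lst.sort(key=lambda item: item[1][1])
    return root, TorsionTree(fragments=fragments, children=children)


# ---------------------------------------------------------------------------
# AutoDock atom types
# ---------------------------------------------------------------------------

def assign_autodock_types(molecule: Molecule) -> None:
    """Minimal AutoDock-style typing: aromatic carbon A; polar hydrogen HD;
    oxygen OA and nitrogen NA as hydrogen-bond acceptors; other elements by
    symbol."""
    aromatic_atoms: set[int] = set()
    for b in molecule.bonds:
        if b.order == AROMATIC:
            aromatic_atoms.update((b.i, b.j))
    for idx, atom in enumerate(molecule.atoms):
        el = atom.element
        if el == "C":
            atom.ad_type = "A" if idx in aromatic_atoms else "C"
        elif el == "H":
            polar = any(
                molecule.atoms[nb].element in ("N", "O", "S")
                for nb in molecule.neighbors(idx)
            )
            atom.ad_type = "HD" if polar else "H"
        elif el == "O":
            atom.ad_type = "OA"
        elif el == "N":
            atom.ad_type = "NA"
        elif el == "S":
            atom.ad_type = "SA"
        else:
            atom.ad_type = el.upper()[:2]


def prepare_ligand(
    molecule: Molecule,
    ligand_id: str = "",
    peoe_iterations: int = DEFAULT_PEOE_ITERATIONS,
    exclude_amides: bool = True,
) -> LigandMolecule:
    """Full ligand preparation: charges, types, rotatable bonds, torsion tree."""
    molecule = mark_aromatic_rings(molecule)
    assign_gasteiger_charges(molecule, iterations=peoe_iterations)
    assign_autodock_types(molecule)
    rotatable = find_rotatable_bonds(molecule, exclude_amides=exclude_amides)
    root, tree = build_torsion_tree(molecule, rotatable)
    return LigandMolecule(
        ligand_id=ligand_id or molecule.name,
        molecule=molecule,
        rotatable_bonds=rotatable,
        torsion_root=root,
        torsion_tree=tree,
    )
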