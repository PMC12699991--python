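"""Charge assignment, rotatable-bond detection, torsion-tree construction.

The PEOE charge oracle is an established cheminformatics toolkit's
implementation run on the same connectivity.
"""

import itertools

import numpy as np
import pytest

from vinascreen.errors import UnsupportedElementError, VinascreenError
from vinascreen.formats import AROMATIC, Bond, Molecule
from vinascreen.ligand_prep import (
    assign_gasteiger_charges,
    build_torsion_tree,
    find_rotatable_bonds,
    infer_hybridizations,
    prepare_ligand,
)

from conftest import alkane, ethanol, make_atom


def rdkit_gasteiger(molecule, n_iter=6):
    """Reference charges from RDKit on an identical explicit-H graph."""
    from rdkit import Chem
    from rdkit.Chem import AllChem

    em = Chem.RWMol()
    for atom in molecule.atoms:
        em.AddAtom(Chem.Atom(atom.element))
    orders = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
              3: Chem.BondType.TRIPLE, AROMATIC: Chem.BondType.AROMATIC}
    for bond in molecule.bonds:
        em.AddBond(bond.i, bond.j, orders[bond.order])
    mol = em.GetMol()
    Chem.SanitizeMol(mol)
    AllChem.ComputeGasteigerCharges(mol, nIter=n_iter)
    return [float(a.GetProp("_GasteigerCharge")) for a in mol.GetAtoms()]


class TestGasteigerCharges:
    @pytest.mark.parametrize("mol_factory", [ethanol, lambda: alkane(4), lambda: alkane(7)])
    def test_charge_conservation(self, mol_factory):
        mol = mol_factory()
        charges = assign_gasteiger_charges(mol)
        assert sum(charges) == pytest.approx(0.0, abs=1e-6)

    def test_methane_symmetry(self):
        mol = alkane(1)
        charges = assign_gasteiger_charges(mol)
        carbon, hydrogens = charges[0], charges[1:]
        assert carbon < 0
        assert all(h > 0 for h in hydrogens)
        assert max(hydrogens) - min(hydrogens) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("mol_factory", [ethanol, lambda: alkane(4)])
    def test_matches_reference_toolkit(self, mol_factory):
        mol = mol_factory()
        ours = assign_gasteiger_charges(mol, iterations=6)
        theirs = rdkit_gasteiger(mol, n_iter=6)
        assert np.abs(np.array(ours) - np.array(theirs)).max() < 5e-3

    def test_relabeling_permutes_charges(self):
        mol = ethanol()
        base = assign_gasteiger_charges(mol)
        perm = list(reversed(range(len(mol.atoms))))
        inv = {p: k for k, p in enumerate(perm)}
        atoms = [mol.atoms[p] for p in perm]
        for a in atoms:
            a.partial_charge = None
        bonds = [Bond(inv[b.i], inv[b.j], b.order) for b in mol.bonds]
        shuffled = Molecule(atoms=atoms, bonds=bonds, name="ethanol-perm")
        assert assign_gasteiger_charges(shuffled) == pytest.approx(
            [base[p] for p in perm], abs=1e-12
        )

    def test_damping_shrinks_transfers(self):
        mol = ethanol()
        previous = None
        deltas = []
        for k in range(1, 9):
            charges = np.array(assign_gasteiger_charges(mol, iterations=k))
            if previous is not None:
                deltas.append(np.abs(charges - previous).sum())
            previous = charges
        assert all(d2 <= d1 + 1e-12 for d1, d2 in zip(deltas, deltas[1:]))

    def test_unsupported_element(self):
        mol = Molecule(atoms=[make_atom("Zn")], bonds=[])
        with pytest.raises(UnsupportedElementError, match="Zn"):
            assign_gasteiger_charges(mol)

    def test_oxygen_is_most_negative_in_ethanol(self):
        mol = ethanol()
        charges = assign_gasteiger_charges(mol)
        assert np.argmin(charges) == 2  # the oxygen


class TestHybridization:
    def test_orders_drive_hybridization(self):
        atoms = [make_atom("C", serial=1), make_atom("C", x=1.2, serial=2),
                 make_atom("C", x=2.7, serial=3)]
        mol = Molecule(atoms=atoms, bonds=[Bond(0, 1, 3), Bond(1, 2, 1)])
        assert infer_hybridizations(mol)[:2] == ["sp", "sp"]
        mol2 = Molecule(atoms=atoms, bonds=[Bond(0, 1, 2), Bond(1, 2, 1)])
        assert infer_hybridizations(mol2)[0] == "sp2"
        assert infer_hybridizations(mol2)[2] == "sp3"


class TestRotatableBonds:
    def test_ethane_terminal(self):
        assert find_rotatable_bonds(alkane(2)) == []

    def test_butane_central_bond(self):
        mol = alkane(4)
        rotatable = find_rotatable_bonds(mol)
        assert [b.key for b in rotatable] == [(1, 2)]

    def test_benzene_ring_excluded(self):
        from vinascreen.fixtures import generate_ligand_fixture
        from vinascreen.formats import read_sdf_v2000

        text, _ = generate_ligand_fixture("rigid-ring", seed=0)
        assert find_rotatable_bonds(read_sdf_v2000(text)) == []

    def test_matches_reference_toolkit_on_chains(self):
        from rdkit import Chem
        from rdkit.Chem import Lipinski

        for n in (2, 4, 6, 8):
            rd = Chem.MolFromSmiles("C" * n)
            assert len(find_rotatable_bonds(alkane(n))) == Lipinski.NumRotatableBonds(rd)

    def test_amide_excluded_by_default(self):
        # CH3-C(=O)-NH-CH3 skeleton with explicit hydrogens
        atoms = [make_atom("C", 0.0, serial=1), make_atom("C", 1.5, serial=2),
                 make_atom("O", 2.1, y=1.1, serial=3), make_atom("N", 2.3, y=-1.1, serial=4),
                 make_atom("C", 3.8, y=-1.2, serial=5)]
        bonds = [Bond(0, 1, 1), Bond(1, 2, 2), Bond(1, 3, 1), Bond(3, 4, 1)]
        h = 5
        for parent, count in ((0, 3), (3, 1), (4, 3)):
            for j in range(count):
                h += 1
                atoms.append(make_atom("H", x=atoms[parent].x + 0.3 * j, y=2.0, serial=h))
                bonds.append(Bond(parent, len(atoms) - 1, 1))
        mol = Molecule(atoms=atoms, bonds=bonds)
        keys = {b.key for b in find_rotatable_bonds(mol)}
        assert (1, 3) not in keys  # the amide C-N
        assert (1, 3) in {b.key for b in find_rotatable_bonds(mol, exclude_amides=False)}


class TestTorsionTree:
    def test_rigid_molecule_single_node(self):
        mol = alkane(2)
        root, tree = build_torsion_tree(mol, [])
        assert len(tree.fragments) == 1
        assert set(tree.fragments[root]) == set(range(len(mol.atoms)))

    def test_butane_two_fragments(self):
        mol = alkane(4)
        rotatable = find_rotatable_bonds(mol)
        root, tree = build_torsion_tree(mol, rotatable)
        assert len(tree.fragments) == 2
        # tie on max branch size -> fragment holding atom index 0 wins
        assert 0 in tree.fragments[root]

    def test_linear_chain_interior_root_brute_force(self):
        mol = alkane(6)
        rotatable = find_rotatable_bonds(mol)
        assert len(rotatable) == 3
        root, tree = build_torsion_tree(mol, rotatable)

        # independent oracle: recompute every fragment's largest-branch size
        # directly on atom sets
        import networkx as nx

        graph = nx.Graph()
        graph.add_nodes_from(range(len(mol.atoms)))
        graph.add_edges_from(b.key for b in mol.bonds)
        cut = graph.copy()
        cut.remove_edges_from(b.key for b in rotatable)
        frags = [tuple(sorted(c)) for c in nx.connected_components(cut)]
        frags.sort(key=lambda f: f[0])

        def branch_size(fi):
            # largest component of the atom graph after removing fragment fi
            rest = graph.subgraph(set(range(len(mol.atoms))) - set(frags[fi]))
            return max((len(c) for c in nx.connected_components(rest)), default=0)

        best = min(range(len(frags)), key=lambda fi: (branch_size(fi), frags[fi][0]))
        assert tree.fragments[root] == frags[best]
        # interior fragment: it touches two rotatable bonds
        touching = sum(
            1 for b in rotatable
            if b.i in tree.fragments[root] or b.j in tree.fragments[root]
        )
        assert touching == 2

    def test_tree_spans_all_atoms(self):
        mol = alkane(7)
        rotatable = find_rotatable_bonds(mol)
        _, tree = build_torsion_tree(mol, rotatable)
        covered = sorted(itertools.chain.from_iterable(tree.fragments))
        assert covered == list(range(len(mol.atoms)))
        n_edges = sum(len(v) for v in tree.children.values())
        assert n_edges == len(rotatable)

    def test_ring_bond_rejected(self):
        from vinascreen.fixtures import generate_ligand_fixture
        from vinascreen.formats import read_sdf_v2000

        text, _ = generate_ligand_fixture("rigid-ring", seed=0)
        mol = read_sdf_v2000(text)
        with pytest.raises(VinascreenError, match="ring"):
            build_torsion_tree(mol, [mol.bonds[0]])


class TestPrepareLigand:
    def test_torsdof_matches_rotatable_count(self):
        from vinascreen.fixtures import generate_ligand_fixture
        from vinascreen.formats import read_sdf_v2000, write_pdbqt_ligand

        for template, _ in (("chain-4", 1), ("chain-6", 3), ("branched", 1)):
            text, expected = generate_ligand_fixture(template, seed=5)
            ligand = prepare_ligand(read_sdf_v2000(text))
            assert len(ligand.rotatable_bonds) == expected
            out = write_pdbqt_ligand(ligand)
            assert sum(1 for l in out.splitlines() if l.startswith("BRANCH")) == expected
            assert out.splitlines()[-1] == f"TORSDOF {expected}"
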