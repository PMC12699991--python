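"""File-format contracts: PDB/PDBQT/SDF parsing, bond perception, Vina output."""

import math
import random

import pytest

from vinascreen.errors import (
    ContractViolationError,
    EmptyInputError,
    EmptyOutputError,
    ParseError,
    UnsupportedElementError,
)
from vinascreen.fixtures import generate_ligand_fixture, generate_receptor_fixture
from vinascreen.formats import (
    AROMATIC,
    Bond,
    Molecule,
    parse_vina_output,
    perceive_bonds,
    read_pdb,
    read_pdbqt_receptor,
    read_sdf_v2000,
    write_pdbqt_receptor,
    write_sdf_v2000,
)
from vinascreen.ligand_prep import prepare_ligand

from conftest import make_atom

PDB_LINE = (
    "ATOM      1  CA  ALA A   1      11.104  13.207   2.100  1.00 91.20           C"
)

ETHANE_SDF = """ethane

  test
  2  1  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.5400    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
M  END
$$$$
"""


class TestReadPdb:
    def test_single_record(self):
        structure = read_pdb(PDB_LINE)
        assert len(structure.residues) == 1
        res = structure.residues[0]
        assert res.plddt == pytest.approx(91.20)
        assert res.atoms[0].coords == pytest.approx((11.104, 13.207, 2.100))
        assert res.atoms[0].element == "C"

    def test_fixture_counts(self):
        text, _ = generate_receptor_fixture(3, 0.0, seed=5)
        structure = read_pdb(text)
        assert len(structure.residues) == 3
        assert len(structure.atoms) == 12

    def test_truncated_coordinates_report_line_number(self):
        bad = PDB_LINE[:40]
        with pytest.raises(ParseError, match="line 1"):
            read_pdb(bad)

    def test_garbled_coordinate_field(self):
        bad = PDB_LINE[:30] + "  xx.yyy" + PDB_LINE[38:]
        with pytest.raises(ParseError, match="line 1"):
            read_pdb(bad)

    def test_empty_input(self):
        with pytest.raises(EmptyInputError):
            read_pdb("HEADER    NOTHING\nEND\n")


class TestReadSdf:
    def test_ethane(self):
        mol = read_sdf_v2000(ETHANE_SDF)
        assert len(mol.atoms) == 2
        assert len(mol.bonds) == 1
        assert mol.bonds[0].order == 1
        assert [a.element for a in mol.atoms] == ["C", "C"]

    def test_benzene_aromatic_flags(self):
        text, _ = generate_ligand_fixture("rigid-ring", seed=3)
        mol = read_sdf_v2000(text)
        assert sum(1 for b in mol.bonds if b.order == AROMATIC) == 6

    def test_counts_mismatch(self):
        bad = ETHANE_SDF.replace("  2  1", "  5  1")
        with pytest.raises(ParseError, match="5 atoms"):
            read_sdf_v2000(bad)

    @pytest.mark.parametrize("template", ["rigid-ring", "chain-4", "chain-6", "branched"])
    def test_round_trip(self, template):
        text, _ = generate_ligand_fixture(template, seed=11)
        mol = read_sdf_v2000(text)
        again = read_sdf_v2000(write_sdf_v2000(mol))
        assert [a.element for a in again.atoms] == [a.element for a in mol.atoms]
        assert sorted((b.key, b.order) for b in again.bonds) == sorted(
            (b.key, b.order) for b in mol.bonds
        )


class TestPerceiveBonds:
    def test_carbons_at_bonding_distance(self):
        atoms = [make_atom("C", 0.0), make_atom("C", 1.54, serial=2)]
        assert len(perceive_bonds(atoms, tolerance=0.45)) == 1

    def test_carbons_far_apart(self):
        atoms = [make_atom("C", 0.0), make_atom("C", 3.0, serial=2)]
        assert perceive_bonds(atoms) == []

    def test_clash_guard(self):
        atoms = [make_atom("C", 0.0), make_atom("C", 0.0, serial=2)]
        assert perceive_bonds(atoms) == []

    def test_unsupported_element(self):
        atoms = [make_atom("Xx", 0.0)]
        with pytest.raises(UnsupportedElementError, match="Xx"):
            perceive_bonds(atoms)

    def test_permutation_invariance(self):
        rnd = random.Random(7)
        atoms = [
            make_atom("C", x=1.5 * k, y=0.2 * (k % 2), serial=k + 1) for k in range(6)
        ]
        bonds = {b.key for b in perceive_bonds(atoms)}
        perm = list(range(6))
        rnd.shuffle(perm)
        shuffled = [atoms[p] for p in perm]
        inv = {p: k for k, p in enumerate(perm)}
        relabeled = {
            tuple(sorted((inv[i], inv[j]))) for i, j in bonds
        }
        assert {b.key for b in perceive_bonds(shuffled)} == relabeled


class TestPdbqt:
    def _prepared(self):
        structure = read_pdb(PDB_LINE)
        atom = structure.residues[0].atoms[0]
        atom.partial_charge = -0.25
        atom.ad_type = "OA"
        return structure

    def test_charge_and_type_columns(self):
        text = write_pdbqt_receptor(self._prepared())
        line = text.splitlines()[0]
        assert line.rstrip().endswith("-0.250 OA")
        assert line[70:76] == "-0.250"
        assert line[77:79] == "OA"

    def test_round_trip_exact(self):
        text = write_pdbqt_receptor(self._prepared())
        again = read_pdbqt_receptor(text)
        atom = again.atoms[0]
        assert f"{atom.x:.3f} {atom.y:.3f} {atom.z:.3f}" == "11.104 13.207 2.100"
        assert f"{atom.partial_charge:.3f}" == "-0.250"
        # second pass: writing the re-read structure reproduces the bytes
        assert write_pdbqt_receptor(again) == text

    def test_unassigned_charge_rejected(self):
        structure = read_pdb(PDB_LINE)
        with pytest.raises(ContractViolationError):
            write_pdbqt_receptor(structure)

    def test_no_branch_records_for_receptor(self):
        text = write_pdbqt_receptor(self._prepared())
        assert "ROOT" not in text and "BRANCH" not in text


class TestLigandPdbqt:
    def test_rigid_ligand(self):
        from vinascreen.formats import write_pdbqt_ligand

        text, _ = generate_ligand_fixture("rigid-ring", seed=1)
        ligand = prepare_ligand(read_sdf_v2000(text))
        out = write_pdbqt_ligand(ligand)
        assert out.count("ROOT") == 2  # ROOT + ENDROOT
        assert "BRANCH" not in out
        assert out.splitlines()[-1] == "TORSDOF 0"

    def test_two_rotatable_bonds(self):
        from vinascreen.formats import write_pdbqt_ligand

        text, expected = generate_ligand_fixture("chain-5", seed=1)
        assert expected == 2
        ligand = prepare_ligand(read_sdf_v2000(text))
        out = write_pdbqt_ligand(ligand)
        branch_lines = [l for l in out.splitlines() if l.startswith("BRANCH")]
        assert len(branch_lines) == 2
        assert out.splitlines()[-1] == "TORSDOF 2"

    def test_branch_pairs_are_the_rotatable_bonds(self):
        from vinascreen.formats import write_pdbqt_ligand

        text, _ = generate_ligand_fixture("chain-6", seed=2)
        ligand = prepare_ligand(read_sdf_v2000(text))
        out = write_pdbqt_ligand(ligand)
        # map written serials back to atom indices via output order
        order = []
        for line in out.splitlines():
            if line.startswith(("ATOM", "HETATM")):
                order.append(line[12:16].strip())
        names = {k + 1: n for k, n in enumerate(order)}
        branch_pairs = set()
        for line in out.splitlines():
            if line.startswith("BRANCH"):
                _, a, b = line.split()
                branch_pairs.add(frozenset((names[int(a)], names[int(b)])))
        rot_pairs = {
            frozenset((ligand.molecule.atoms[b.i].name, ligand.molecule.atoms[b.j].name))
            for b in ligand.rotatable_bonds
        }
        assert branch_pairs == rot_pairs

    def test_torsion_tree_required(self):
        from vinascreen.formats import write_pdbqt_ligand
        from vinascreen.ligand_prep import LigandMolecule

        text, _ = generate_ligand_fixture("chain-4", seed=1)
        bare = LigandMolecule(ligand_id="x", molecule=read_sdf_v2000(text))
        with pytest.raises(ContractViolationError):
            write_pdbqt_ligand(bare)


class TestVinaOutput:
    def test_single_result_line(self):
        poses = parse_vina_output(
            "REMARK VINA RESULT:    -9.1      0.000      0.000\n"
        )
        assert len(poses) == 1
        assert poses[0].mode_index == 1
        assert poses[0].energy == pytest.approx(-9.1)
        assert poses[0].rmsd_lb == 0.0

    def test_order_preserved(self):
        text = "".join(
            f"REMARK VINA RESULT: {e} 0.0 1.2\n" for e in (-9.1, -8.725, -7.5)
        )
        poses = parse_vina_output(text)
        assert [p.energy for p in poses] == [-9.1, -8.725, -7.5]
        assert [p.mode_index for p in poses] == [1, 2, 3]

    def test_any_decimal_precision(self):
        poses = parse_vina_output("REMARK VINA RESULT: -11.200 0.000 0.000\n")
        assert poses[0].energy == pytest.approx(-11.2)

    def test_no_result_lines_is_an_error(self):
        with pytest.raises(EmptyOutputError):
            parse_vina_output("MODEL 1\nENDMDL\n")


class TestMoleculeInvariants:
    def test_bond_out_of_range(self):
        with pytest.raises(ValueError):
            Molecule(atoms=[make_atom("C")], bonds=[Bond(0, 1)])

    def test_duplicate_bond(self):
        atoms = [make_atom("C"), make_atom("C", 1.5, serial=2)]
        with pytest.raises(ValueError):
            Molecule(atoms=atoms, bonds=[Bond(0, 1), Bond(1, 0)])

    def test_self_bond(self):
        with pytest.raises(ValueError):
            Bond(2, 2)
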