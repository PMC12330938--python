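"""Parsing, frame selection, altloc policy and sequence extraction."""

import numpy as np
import pytest

import metconf as mc
from metconf.model import AtomRecord, ResidueRecord, StructureModel
from metconf.synthetic import template_atoms

from conftest import simple_recipe


def _make_model(residues, entry="toy", chain="A"):
    return StructureModel(entry_id=entry, models=[{chain: residues}], source_format="memory")


def _residue(num, aa3, atoms=None, icode="", het=False):
    if atoms is None:
        atoms = [
            AtomRecord(n, "C" if n not in ("N",) else "N", tuple(xyz + [num * 8.0, 0, 0]))
            for n, xyz in template_atoms(aa3)
        ]
    return ResidueRecord(num, icode, aa3, atoms, het)


class TestReadStructure:
    def test_six_residue_fixture_inventory(self, cfg, tmp_path):
        plan = [(1, "HIS"), (2, "ASP"), (3, "LYS"), (4, "GLU"), (5, "LEU"), (6, "VAL")]
        recipe = mc.FixtureRecipe(name="six", targets={}, plan=plan)
        sm = mc.build_fixture(recipe, cfg)
        path = tmp_path / "six.pdb"
        mc.write_pdb(sm, str(path))
        parsed = mc.read_structure(str(path))
        residues = parsed.polymer_residues(1, parsed.chain_ids()[0])
        assert len(residues) == 6
        assert [r.aa3 for r in residues] == [aa for _, aa in plan]

    def test_pdb_and_mmcif_dialects_agree(self, cfg, tmp_path):
        sm = mc.build_fixture(simple_recipe(), cfg)
        pdb, cif = tmp_path / "f.pdb", tmp_path / "f.cif"
        mc.write_pdb(sm, str(pdb))
        mc.write_mmcif(sm, str(cif))
        a = mc.read_structure(str(pdb))
        b = mc.read_structure(str(cif))
        ra = a.polymer_residues(1, a.chain_ids()[0])
        rb = b.polymer_residues(1, b.chain_ids()[0])
        assert [(r.author_number, r.aa3) for r in ra] == [(r.author_number, r.aa3) for r in rb]
        for x, y in zip(ra, rb):
            assert [at.name for at in x.atoms] == [at.name for at in y.atoms]
            np.testing.assert_allclose(
                np.stack([at.xyz for at in x.atoms]),
                np.stack([at.xyz for at in y.atoms]),
                atol=1e-3,
            )

    def test_waters_stripped_heteroatoms_flagged(self, cfg, tmp_path):
        sm = mc.build_fixture(simple_recipe(), cfg)
        path = tmp_path / "het.pdb"
        mc.write_pdb(sm, str(path))
        with open(path) as fh:
            lines = fh.read().splitlines()
        extra = [
            "HETATM 9901  O   HOH A5001      99.000  99.000  99.000  1.00  0.00           O",
            "HETATM 9902  PG  ATP A5002      88.000  88.000  88.000  1.00  0.00           P",
            "HETATM 9903  O1G ATP A5002      89.000  88.500  88.000  1.00  0.00           O",
        ]
        lines = lines[:-1] + extra + ["END"]
        path.write_text("\n".join(lines) + "\n")
        parsed = mc.read_structure(str(path))
        het = parsed.hetero_groups()
        names = {r.aa3 for _, r in het}
        assert "ATP" in names and "HOH" not in names
        assert parsed.atom_count() == parsed.atom_count(polymer_only=True) + 2

    def test_unreadable_file_raises_parse_error(self, tmp_path):
        with pytest.raises(mc.StructureParseError):
            mc.read_structure(str(tmp_path / "nope.pdb"))

    def test_zero_polymer_atoms_raises_empty_error(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("HEADER    NOTHING\nEND\n")
        with pytest.raises(mc.StructureError):
            mc.read_structure(str(path))

    def test_parse_twice_is_structurally_equal(self, cfg, tmp_path):
        sm = mc.build_fixture(simple_recipe(), cfg)
        path = tmp_path / "det.pdb"
        mc.write_pdb(sm, str(path))
        a, b = mc.read_structure(str(path)), mc.read_structure(str(path))
        assert a.atom_count() == b.atom_count()
        ra = a.polymer_residues(1, a.chain_ids()[0])
        rb = b.polymer_residues(1, b.chain_ids()[0])
        assert all(
            x.key() == y.key() and [p.coords for p in x.atoms] == [q.coords for q in y.atoms]
            for x, y in zip(ra, rb)
        )

    def test_round_trip_write_read_write(self, cfg, tmp_path):
        sm = mc.build_fixture(simple_recipe(), cfg)
        p1, p2 = tmp_path / "a.pdb", tmp_path / "b.pdb"
        mc.write_pdb(sm, str(p1))
        again = mc.read_structure(str(p1))
        mc.write_pdb(again, str(p2))
        r1 = mc.read_structure(str(p1))
        r2 = mc.read_structure(str(p2))
        a = r1.polymer_residues(1, r1.chain_ids()[0])
        b = r2.polymer_residues(1, r2.chain_ids()[0])
        assert [(r.author_number, r.aa3) for r in a] == [(r.author_number, r.aa3) for r in b]
        for x, y in zip(a, b):
            np.testing.assert_allclose(
                np.stack([at.xyz for at in x.atoms]),
                np.stack([at.xyz for at in y.atoms]),
                atol=1e-3,
            )

    def test_cross_parser_inventory_against_biotite(self, cfg, tmp_path):
        biotite_pdb = pytest.importorskip("biotite.structure.io.pdb")
        sm = mc.build_fixture(simple_recipe(), cfg)
        path = tmp_path / "x.pdb"
        mc.write_pdb(sm, str(path))
        ref = biotite_pdb.PDBFile.read(str(path)).get_structure(model=1)
        mine = mc.read_structure(str(path))
        assert mine.atom_count() == ref.array_length()
        assert mine.residue_count() == len(set(zip(ref.chain_id, ref.res_id)))


class TestSelectFrame:
    def test_second_chain_holds_bridge_residues(self, cfg):
        sm = mc.build_fixture(simple_recipe(incomplete_first_chain=True), cfg)
        frame = mc.select_frame(sm, 1, required_position_sets=cfg.required_position_sets())
        assert frame.chain_id == "B"

    def test_selection_error_lists_missing_positions(self, cfg):
        sm = mc.build_fixture(
            mc.FixtureRecipe(name="none", targets={}, plan=[(1, "GLY"), (2, "ALA")]), cfg
        )
        with pytest.raises(mc.SelectionError, match="missing"):
            mc.select_frame(sm, 1, required_position_sets=cfg.required_position_sets())

    def test_altloc_highest_occupancy_wins(self, cfg):
        sm = mc.build_fixture(
            simple_recipe(altlocs=(mc.AltlocDuplicate(1086, "NE2", (0.3, 0.7)),)), cfg
        )
        frame = mc.select_frame(sm, 1)
        ne2 = [a for a in frame.residue_at(1086).atoms if a.name == "NE2"]
        assert len(ne2) == 1 and ne2[0].occupancy == 0.7

    def test_altloc_tie_first_in_file_wins(self, cfg):
        sm = mc.build_fixture(
            simple_recipe(altlocs=(mc.AltlocDuplicate(1086, "NE2", (0.5, 0.5)),)), cfg
        )
        res = sm.models[0]["A"][[r.author_number for r in sm.models[0]["A"]].index(1086)]
        first = next(a for a in res.atoms if a.name == "NE2")
        frame = mc.select_frame(sm, 1)
        kept = next(a for a in frame.residue_at(1086).atoms if a.name == "NE2")
        assert kept.coords == first.coords

    def test_deterministic_across_runs(self, cfg, tmp_path):
        sm = mc.build_fixture(simple_recipe(incomplete_first_chain=True), cfg)
        path = tmp_path / "sel.pdb"
        mc.write_pdb(sm, str(path))
        frames = [
            mc.select_frame(mc.read_structure(str(path)), 1,
                            required_position_sets=cfg.required_position_sets())
            for _ in range(2)
        ]
        assert frames[0].chain_id == frames[1].chain_id
        assert [r.key() for r in frames[0].residues] == [r.key() for r in frames[1].residues]


class TestChainSequence:
    def test_author_indexed_one_letter_codes(self):
        residues = [_residue(1068, "HIS"), _residue(1133, "ASP")]
        seq = mc.chain_sequence(residues)
        assert seq.mapping == {1068: "H", 1133: "D"}

    def test_nonstandard_residue_maps_to_x(self):
        residues = [_residue(5, "MSE")]
        assert mc.chain_sequence(residues).mapping == {5: "X"}

    def test_numbering_gap_reported_absent_not_padded(self):
        residues = [_residue(1068, "HIS"), _residue(1133, "ASP")]
        seq = mc.chain_sequence(residues)
        assert seq.absent_positions == list(range(1069, 1133))
        assert len(seq.mapping) == 2
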