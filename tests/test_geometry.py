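"""Bridge distances: grid minimum vs brute force, invariances, scans."""

import numpy as np
import pytest

import metconf as mc
from metconf.geometry import measure_bridge, measure_contact, polar_neighbor_scan
from metconf.model import AtomRecord, ResidueRecord
from metconf.numbering import NumberingResolution
from metconf.synthetic import template_atoms

from conftest import random_rotation

RES0 = NumberingResolution(status="resolved", offset=0)


def _residue(num, aa3, origin, jitter=None):
    atoms = []
    for n, xyz in template_atoms(aa3):
        p = np.asarray(xyz) + np.asarray(origin, float)
        if jitter is not None:
            p = p + jitter.uniform(-0.3, 0.3, 3)
        atoms.append(AtomRecord(n, "SE" if (aa3, n) == ("MSE", "SE") else n[0], tuple(p)))
    return ResidueRecord(num, "", aa3, atoms)


def _bridge_spec(dpos=1086, daa="H", datoms=("ND1", "NE2"),
                 apos=1151, aaa="D", aatoms=("OD1", "OD2"), cutoff=4.0):
    return mc.SaltBridgeSpec(
        "HD",
        mc.BridgeEnd(mc.ResidueSpec(dpos, daa), tuple(datoms)),
        mc.BridgeEnd(mc.ResidueSpec(apos, aaa), tuple(aatoms)),
        cutoff,
    )


def brute_force_min_no_pair(donor, acceptor):
    """Independent oracle: exhaustive loop over side-chain N x O atoms."""
    best = None
    for a in donor.atoms:
        if a.name in ("N", "CA", "C", "O") or not a.name.startswith("N"):
            continue
        for b in acceptor.atoms:
            if b.name in ("N", "CA", "C", "O") or not b.name.startswith("O"):
                continue
            d = float(np.sqrt(sum((x - y) ** 2 for x, y in zip(a.coords, b.coords))))
            if best is None or d < best:
                best = d
    return best


class TestMeasureBridge:
    def test_exact_placement_min_pair(self):
        his = ResidueRecord(1086, "", "HIS", [
            AtomRecord("ND1", "N", (0.0, 0.0, 0.0)),
            AtomRecord("NE2", "N", (0.0, 6.0, 0.0)),
        ])
        asp = ResidueRecord(1151, "", "ASP", [
            AtomRecord("OD1", "O", (3.0, 0.0, 0.0)),
            AtomRecord("OD2", "O", (8.0, 0.0, 0.0)),
        ])
        m = measure_bridge([his, asp], RES0, _bridge_spec())
        assert m.measurable and m.present
        assert m.min_pair == ("ND1", "OD1")
        assert m.min_distance == pytest.approx(3.0, abs=1e-9)

    def test_grid_min_equals_brute_force_on_random_fixtures(self):
        rng = np.random.default_rng(7)
        spec = _bridge_spec()
        for _ in range(120):
            his = _residue(1086, "HIS", rng.uniform(-5, 5, 3), jitter=rng)
            asp = _residue(1151, "ASP", rng.uniform(-5, 5, 3), jitter=rng)
            m = measure_bridge([his, asp], RES0, spec)
            assert m.measurable
            assert m.min_distance == pytest.approx(
                brute_force_min_no_pair(his, asp), abs=1e-9
            )
            assert all(m.min_distance <= v for v in m.all_pairs.values())

    def test_swapping_donor_acceptor_preserves_min_distance(self):
        rng = np.random.default_rng(3)
        his = _residue(1086, "HIS", (0, 0, 0), jitter=rng)
        asp = _residue(1151, "ASP", (4, 1, -2), jitter=rng)
        fwd = measure_bridge([his, asp], RES0, _bridge_spec())
        rev = measure_bridge([his, asp], RES0, _bridge_spec(
            dpos=1151, daa="D", datoms=("OD1", "OD2"),
            apos=1086, aaa="H", aatoms=("ND1", "NE2")))
        assert fwd.min_distance == pytest.approx(rev.min_distance, abs=1e-12)

    def test_rigid_body_invariance(self):
        rng = np.random.default_rng(11)
        his = _residue(1086, "HIS", (0, 0, 0), jitter=rng)
        asp = _residue(1151, "ASP", (3, 2, 1), jitter=rng)
        base = measure_bridge([his, asp], RES0, _bridge_spec())
        for _ in range(10):
            rot = random_rotation(rng)
            shift = rng.uniform(-50, 50, 3)
            moved = []
            for r in (his, asp):
                atoms = [
                    AtomRecord(a.name, a.element, tuple(rot @ np.asarray(a.coords) + shift))
                    for a in r.atoms
                ]
                moved.append(ResidueRecord(r.author_number, "", r.aa3, atoms))
            m = measure_bridge(moved, RES0, _bridge_spec())
            assert m.min_distance == pytest.approx(base.min_distance, abs=1e-6)

    def test_missing_atoms_unmeasurable(self):
        his = ResidueRecord(1086, "", "HIS", [AtomRecord("CA", "C", (0, 0, 0))])
        asp = _residue(1151, "ASP", (4, 0, 0))
        m = measure_bridge([his, asp], RES0, _bridge_spec())
        assert not m.measurable and not m.present
        assert m.all_pairs == {}


class TestMeasureContact:
    def test_side_chains_within_cutoff_present(self):
        a = ResidueRecord(1080, "", "LEU", [
            AtomRecord("CA", "C", (0, 0, 0)), AtomRecord("CD1", "C", (0, 0, 2.0))])
        b = ResidueRecord(1143, "", "LEU", [
            AtomRecord("CA", "C", (20, 0, 0)), AtomRecord("CD1", "C", (0, 0, 6.0))])
        spec = mc.ContactSpec(mc.ResidueSpec(1080, "L"), mc.ResidueSpec(1143, "L"), 4.5)
        m = measure_contact([a, b], RES0, spec)
        assert m.present and m.min_distance == pytest.approx(4.0)
        assert m.min_pair == ("CD1", "CD1")

    def test_side_chains_beyond_cutoff_absent(self):
        a = ResidueRecord(1080, "", "LEU", [
            AtomRecord("CA", "C", (0, 0, 0)), AtomRecord("CD1", "C", (0, 0, 0))])
        b = ResidueRecord(1143, "", "LEU", [
            AtomRecord("CA", "C", (0, 0, 9)), AtomRecord("CD1", "C", (0, 0, 6.0))])
        spec = mc.ContactSpec(mc.ResidueSpec(1080, "L"), mc.ResidueSpec(1143, "L"), 4.5)
        m = measure_contact([a, b], RES0, spec)
        assert m.measurable and not m.present

    def test_backbone_atoms_excluded_from_contact(self):
        a = ResidueRecord(1080, "", "LEU", [
            AtomRecord("CA", "C", (0, 0, 0)), AtomRecord("CD1", "C", (0, 0, 10.0))])
        b = ResidueRecord(1143, "", "LEU", [
            AtomRecord("CA", "C", (0, 0, 1.0)), AtomRecord("CD1", "C", (0, 0, 20.0))])
        spec = mc.ContactSpec(mc.ResidueSpec(1080, "L"), mc.ResidueSpec(1143, "L"), 4.5)
        m = measure_contact([a, b], RES0, spec)
        assert m.min_distance == pytest.approx(10.0)


class TestPolarNeighborScan:
    def test_polarity_filter_drops_apolar_neighbors(self):
        center = ResidueRecord(1102, "", "ILE", [
            AtomRecord("CA", "C", (0, 0, 0)), AtomRecord("CD1", "C", (0, 0, 0))])
        his = ResidueRecord(1112, "", "HIS", [
            AtomRecord("CA", "C", (9, 0, 0)), AtomRecord("NE2", "N", (5.0, 0, 0))])
        leu = ResidueRecord(1120, "", "LEU", [
            AtomRecord("CA", "C", (9, 0, 0)), AtomRecord("CD1", "C", (3.0, 0, 0))])
        hits = polar_neighbor_scan([center, his, leu], RES0, 1102, 6.0)
        assert [(h.paper_position, h.aa1) for h in hits] == [(1112, "H")]
        assert hits[0].min_distance == pytest.approx(5.0)

    def test_degenerate_radius_returns_empty(self, cfg, inactive_model):
        frame = mc.select_frame(inactive_model, 1)
        res = NumberingResolution(status="resolved", offset=0)
        assert polar_neighbor_scan(frame.residues, res, 1102, 0.5) == []

    def test_unobserved_center_returns_none(self):
        lone = ResidueRecord(1120, "", "HIS", [AtomRecord("NE2", "N", (0, 0, 0))])
        assert polar_neighbor_scan([lone], RES0, 1102, 10.0) is None

    def test_results_sorted_by_distance(self):
        center = ResidueRecord(1102, "", "ILE", [AtomRecord("CD1", "C", (0, 0, 0))])
        near = ResidueRecord(1112, "", "HIS", [AtomRecord("NE2", "N", (2.0, 0, 0))])
        far = ResidueRecord(1124, "", "HIS", [AtomRecord("NE2", "N", (4.0, 0, 0))])
        hits = polar_neighbor_scan([center, far, near], RES0, 1102, 10.0)
        assert [h.paper_position for h in hits] == [1112, 1124]
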