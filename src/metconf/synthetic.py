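"""Synthetic kinase-like fixtures with prescribed salt-bridge geometry.

The classifier consumes only local side-chain geometry, so fixtures are
deliberately sparse: one residue per configured marker position (plus
optional decoys), placed far apart on a grid, with the two bridge partners
positioned analytically so that the minimum donor–acceptor N–O distance
equals a requested target exactly (before the 0.001 Å PDB column
rounding).  No rotamer library, no backbone continuity, no energetics —
distances are the only controlled observable.

Placement of an acceptor residue: take the donor atom D farthest from the
donor Cα, extend along the unit vector u from Cα through D, rotate the
acceptor template so its own Cα points onward along u, and put the
acceptor atom at D + d·u.  Every other donor atom then lies behind D and
every other acceptor atom beyond the acceptor atom, so the designed pair
is provably the grid minimum; the builder re-measures and refuses to emit
a fixture where that guarantee fails.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .config import Config
from .io import write_mmcif, write_pdb
from .model import AA1_TO_3, AtomRecord, ChainMap, ResidueRecord, StructureModel

MIN_TARGET = 1.5  # Å; anything closer is a physically meaningless clash


class GenerationError(ValueError):
    """Recipe cannot be realized (clashing or conflicting demands)."""


# --------------------------------------------------------------------------
# idealized residue templates (coordinates relative to CA, Å)

_BB = [("N", (-1.458, 0.30, 0.0)), ("CA", (0.0, 0.0, 0.0)),
       ("C", (0.55, 1.42, 0.0)), ("O", (1.77, 1.56, 0.0))]

_CB = np.array([-0.53, -0.77, -1.20])
_S1 = np.array([0.0, -1.30, -0.78])


def _t(*vecs) -> Tuple[float, float, float]:
    return tuple(float(x) for x in np.sum(vecs, axis=0))


_CG = _CB + _S1
_SIDE: Dict[str, List[Tuple[str, Tuple[float, float, float]]]] = {
    "GLY": [],
    "ALA": [("CB", _t(_CB))],
    "SER": [("CB", _t(_CB)), ("OG", _t(_CB, _S1))],
    "CYS": [("CB", _t(_CB)), ("SG", _t(_CB, (0, -1.60, -0.95)))],
    "THR": [("CB", _t(_CB)), ("OG1", _t(_CB, (1.20, -0.70, -0.30))),
            ("CG2", _t(_CB, (-1.20, -0.80, -0.30)))],
    "VAL": [("CB", _t(_CB)), ("CG1", _t(_CB, (1.20, -0.80, -0.30))),
            ("CG2", _t(_CB, (-1.20, -0.80, -0.30)))],
    "LEU": [("CB", _t(_CB)), ("CG", _t(_CG)),
            ("CD1", _t(_CG, (1.10, -0.90, 0))), ("CD2", _t(_CG, (-1.10, -0.90, 0)))],
    "ILE": [("CB", _t(_CB)), ("CG1", _t(_CB, _S1)),
            ("CG2", _t(_CB, (1.30, -0.50, 0.30))), ("CD1", _t(_CB, _S1, _S1))],
    "PRO": [("CB", _t(_CB)), ("CG", _t(_CB, (1.20, -0.80, 0.30))),
            ("CD", _t(_CB, (1.80, 0.50, 0.60)))],
    "MET": [("CB", _t(_CB)), ("CG", _t(_CG)), ("SD", _t(_CG, (0, -1.55, -0.95))),
            ("CE", _t(_CG, (0, -3.10, -1.90)))],
    "MSE": [("CB", _t(_CB)), ("CG", _t(_CG)), ("SE", _t(_CG, (0, -1.55, -0.95))),
            ("CE", _t(_CG, (0, -3.10, -1.90)))],
    "PHE": [("CB", _t(_CB)), ("CG", _t(_CG)),
            ("CD1", _t(_CG, (1.20, -0.70, 0))), ("CD2", _t(_CG, (-1.20, -0.70, 0))),
            ("CE1", _t(_CG, (1.20, -2.10, 0))), ("CE2", _t(_CG, (-1.20, -2.10, 0))),
            ("CZ", _t(_CG, (0, -2.80, 0)))],
    "TYR": [("CB", _t(_CB)), ("CG", _t(_CG)),
            ("CD1", _t(_CG, (1.20, -0.70, 0))), ("CD2", _t(_CG, (-1.20, -0.70, 0))),
            ("CE1", _t(_CG, (1.20, -2.10, 0))), ("CE2", _t(_CG, (-1.20, -2.10, 0))),
            ("CZ", _t(_CG, (0, -2.80, 0))), ("OH", _t(_CG, (0, -4.20, 0)))],
    "TRP": [("CB", _t(_CB)), ("CG", _t(_CG)),
            ("CD1", _t(_CG, (1.20, -0.70, 0))), ("CD2", _t(_CG, (-1.20, -0.70, 0))),
            ("NE1", _t(_CG, (1.40, -2.10, 0))), ("CE2", _t(_CG, (-0.10, -2.20, 0))),
            ("CE3", _t(_CG, (-2.40, -1.30, 0))), ("CZ2", _t(_CG, (-0.10, -3.60, 0))),
            ("CZ3", _t(_CG, (-2.40, -2.70, 0))), ("CH2", _t(_CG, (-1.30, -4.30, 0)))],
    "ASP": [("CB", _t(_CB)), ("CG", _t(_CG)),
            ("OD1", _t(_CG, (1.10, -0.60, 0))), ("OD2", _t(_CG, (-1.10, -0.60, 0)))],
    "ASN": [("CB", _t(_CB)), ("CG", _t(_CG)),
            ("OD1", _t(_CG, (1.10, -0.60, 0))), ("ND2", _t(_CG, (-1.10, -0.60, 0)))],
    "GLU": [("CB", _t(_CB)), ("CG", _t(_CG)), ("CD", _t(_CG, _S1)),
            ("OE1", _t(_CG, _S1, (1.10, -0.60, 0))), ("OE2", _t(_CG, _S1, (-1.10, -0.60, 0)))],
    "GLN": [("CB", _t(_CB)), ("CG", _t(_CG)), ("CD", _t(_CG, _S1)),
            ("OE1", _t(_CG, _S1, (1.10, -0.60, 0))), ("NE2", _t(_CG, _S1, (-1.10, -0.60, 0)))],
    "LYS": [("CB", _t(_CB)), ("CG", _t(_CG)), ("CD", _t(_CG, _S1)),
            ("CE", _t(_CG, _S1, _S1)), ("NZ", _t(_CG, _S1, _S1, _S1))],
    "ARG": [("CB", _t(_CB)), ("CG", _t(_CG)), ("CD", _t(_CG, _S1)),
            ("NE", _t(_CG, _S1, _S1)), ("CZ", _t(_CG, _S1, _S1, _S1)),
            ("NH1", _t(_CG, _S1, _S1, _S1, (1.10, -0.60, 0))),
            ("NH2", _t(_CG, _S1, _S1, _S1, (-1.10, -0.60, 0)))],
    "HIS": [("CB", _t(_CB)), ("CG", _t(_CG)),
            ("ND1", _t(_CG, (1.10, -0.70, 0.10))), ("CD2", _t(_CG, (-1.10, -0.72, 0.10))),
            ("CE1", _t(_CG, (1.35, -2.00, 0.20))), ("NE2", _t(_CG, (-0.80, -2.00, 0.20)))],
}


def _element_of(name: str, aa3: str) -> str:
    if aa3 == "MSE" and name == "SE":
        return "SE"
    return name[0]


def template_atoms(aa3: str) -> List[Tuple[str, np.ndarray]]:
    if aa3 not in _SIDE:
        raise GenerationError(f"no template for residue {aa3}")
    out = [(n, np.asarray(v, float)) for n, v in _BB]
    out += [(n, np.asarray(v, float)) for n, v in _SIDE[aa3]]
    return out


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix sending unit vector a to unit vector b (Rodrigues)."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # opposite: rotate pi around any perpendicular axis
        perp = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        v = np.cross(a, perp)
        v /= np.linalg.norm(v)
        return -np.eye(3) + 2.0 * np.outer(v, v)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


# --------------------------------------------------------------------------
# recipes


@dataclass(frozen=True)
class AltlocDuplicate:
    """Duplicate one atom into two conformers (A first in file, then B)."""

    author_position: int
    atom: str
    occupancies: Tuple[float, float] = (0.5, 0.5)
    displacement: float = 1.2  # Å applied to conformer B


@dataclass
class FixtureRecipe:
    name: str
    targets: Dict[str, float]  # bridge name -> designed min distance, Å
    numbering_offset: int = 0
    chain_id: str = "A"
    plan: Optional[List[Tuple[int, str]]] = None  # (author number, aa3); default: config markers
    mutations: Dict[int, str] = field(default_factory=dict)  # author number -> aa3
    drop_side_chains: Tuple[int, ...] = ()
    altlocs: Tuple[AltlocDuplicate, ...] = ()
    incomplete_first_chain: bool = False
    extra_model: bool = False
    seed: int = 0


def _default_plan(config: Config, offset: int) -> List[Tuple[int, str]]:
    return [
        (s.paper_position + offset, AA1_TO_3[s.expected_aa])
        for s in config.residue_specs
    ]


def build_fixture(recipe: FixtureRecipe, config: Config) -> StructureModel:
    """Realize a recipe as an in-memory structure (deterministic per seed)."""
    for bname, d in recipe.targets.items():
        if bname not in {b.name for b in config.bridges}:
            raise GenerationError(f"{recipe.name}: unknown bridge {bname!r}")
        if d < MIN_TARGET:
            raise GenerationError(
                f"{recipe.name}: target {d} Å for {bname} below clash limit {MIN_TARGET} Å"
            )

    offset = recipe.numbering_offset
    plan = list(recipe.plan) if recipe.plan is not None else _default_plan(config, offset)
    if len({p for p, _ in plan}) != len(plan):
        raise GenerationError(f"{recipe.name}: duplicate author positions in plan")
    aa_by_pos = {p: aa for p, aa in plan}
    for pos, aa3 in recipe.mutations.items():
        if pos not in aa_by_pos:
            raise GenerationError(f"{recipe.name}: mutation at unplanned position {pos}")
        aa_by_pos[pos] = aa3

    bridge_roles: Dict[int, Tuple[str, str]] = {}  # author pos -> (bridge, role)
    for b in config.bridges:
        if b.name not in recipe.targets:
            continue
        dpos = b.donor.spec.paper_position + offset
        apos = b.acceptor.spec.paper_position + offset
        for pos, role in ((dpos, "donor"), (apos, "acceptor")):
            if pos not in aa_by_pos:
                raise GenerationError(
                    f"{recipe.name}: bridge {b.name} needs position {pos} in the plan"
                )
            if pos in bridge_roles:
                raise GenerationError(
                    f"{recipe.name}: conflicting demands on position {pos}"
                )
            bridge_roles[pos] = (b.name, role)

    rng = np.random.default_rng(recipe.seed)
    coords: Dict[int, List[Tuple[str, str, np.ndarray]]] = {}

    # grid for non-bridge residues: 12 Å apart along x, seeded jitter in y/z
    ordinary = [p for p in sorted(aa_by_pos) if p not in bridge_roles]
    for i, pos in enumerate(ordinary):
        base = np.array([12.0 * i, 0.0, 0.0])
        base[1:] += rng.uniform(-1.0, 1.0, size=2)
        aa3 = aa_by_pos[pos]
        coords[pos] = [
            (n, _element_of(n, aa3), xyz + base) for n, xyz in template_atoms(aa3)
        ]

    # bridge pairs: donor anchored, acceptor placed analytically
    for j, b in enumerate(config.bridges):
        if b.name not in recipe.targets:
            continue
        d_target = float(recipe.targets[b.name])
        dpos = b.donor.spec.paper_position + offset
        apos = b.acceptor.spec.paper_position + offset
        daa = aa_by_pos[dpos]
        aaa = aa_by_pos[apos]
        anchor = np.array([50.0 * j, 40.0, 0.0])
        datoms = [(n, _element_of(n, daa), xyz + anchor) for n, xyz in template_atoms(daa)]
        coords[dpos] = datoms
        named = {n: xyz for n, _, xyz in datoms}
        donor_sites = [a for a in b.donor.atoms if a in named]
        if donor_sites:
            dname = max(donor_sites, key=lambda a: np.linalg.norm(named[a] - anchor))
            dxyz = named[dname]
            u = dxyz - anchor
            u /= np.linalg.norm(u)
        else:  # mutated donor without bridging atoms: geometry is moot
            dxyz = anchor
            u = np.array([0.0, -1.0, 0.0])

        tmpl = {n: xyz for n, xyz in template_atoms(aaa)}
        acc_sites = [a for a in b.acceptor.atoms if a in tmpl]
        if acc_sites:
            pname = max(acc_sites, key=lambda a: np.linalg.norm(tmpl[a]))
            p = tmpl[pname]
            rot = _rotation_between(-p, u)  # acceptor CA continues along u
            origin = dxyz + d_target * u
            coords[apos] = [
                (n, _element_of(n, aaa), origin + rot @ (xyz - p))
                for n, xyz in template_atoms(aaa)
            ]
        else:
            base = dxyz + (d_target + 8.0) * u
            coords[apos] = [
                (n, _element_of(n, aaa), xyz + base) for n, xyz in template_atoms(aaa)
            ]

    # perturbations applied on final coordinates
    drop = set(recipe.drop_side_chains)
    residues: List[ResidueRecord] = []
    for pos in sorted(coords):
        aa3 = aa_by_pos[pos]
        atoms: List[AtomRecord] = []
        for n, elem, xyz in coords[pos]:
            if pos in drop and n not in ("N", "CA", "C", "O"):
                continue
            dup = next(
                (al for al in recipe.altlocs
                 if al.author_position == pos and al.atom == n), None,
            )
            xyz_r = np.round(xyz, 3)
            if dup is not None:
                shifted = np.round(xyz + np.array([dup.displacement, 0.0, 0.0]), 3)
                atoms.append(AtomRecord(n, elem, tuple(xyz_r), "A", dup.occupancies[0]))
                atoms.append(AtomRecord(n, elem, tuple(shifted), "B", dup.occupancies[1]))
            else:
                atoms.append(AtomRecord(n, elem, tuple(xyz_r), "", 1.0))
        residues.append(ResidueRecord(pos, "", aa3, atoms))

    chains: ChainMap = {}
    if recipe.incomplete_first_chain:
        # a preceding chain that lacks the bridge positions entirely
        decoys = []
        for i, (pos, aa3) in enumerate([(10, "GLY"), (11, "ALA"), (12, "LEU")]):
            base = np.array([-40.0 + 8.0 * i, -40.0, 0.0])
            decoys.append(ResidueRecord(pos, "", aa3, [
                AtomRecord(n, _element_of(n, aa3), tuple(np.round(xyz + base, 3)), "", 1.0)
                for n, xyz in template_atoms(aa3)
            ]))
        chains["A"] = decoys
        chains["B" if recipe.chain_id == "A" else recipe.chain_id] = residues
    else:
        chains[recipe.chain_id] = residues

    models = [chains]
    if recipe.extra_model:
        shifted_chains: ChainMap = {}
        for cid, rs in chains.items():
            shifted_chains[cid] = [
                ResidueRecord(r.author_number, r.insertion_code, r.aa3, [
                    AtomRecord(a.name, a.element,
                               (a.coords[0] + 100.0, a.coords[1], a.coords[2]),
                               a.altloc, a.occupancy)
                    for a in r.atoms
                ], r.is_hetero)
                for r in rs
            ]
        models.append(shifted_chains)

    sm = StructureModel(entry_id=recipe.name, models=models, source_format="memory")
    _verify_targets(sm, recipe, config)
    return sm


def _verify_targets(sm: StructureModel, recipe: FixtureRecipe, config: Config) -> None:
    """Re-measure every designed bridge; refuse to emit broken geometry."""
    from .geometry import measure_bridge
    from .io import select_frame
    from .numbering import NumberingResolution

    if not recipe.targets:
        return
    frame = select_frame(sm, 1, required_position_sets=config.required_position_sets())
    resolution = NumberingResolution(status="resolved", offset=recipe.numbering_offset)
    mutated_or_dropped = set(recipe.drop_side_chains) | set(recipe.mutations)
    altloc_positions = {al.author_position for al in recipe.altlocs}
    for b in config.bridges:
        if b.name not in recipe.targets:
            continue
        ends = {b.donor.spec.paper_position + recipe.numbering_offset,
                b.acceptor.spec.paper_position + recipe.numbering_offset}
        if ends & mutated_or_dropped:
            continue  # distance deliberately not realizable
        m = measure_bridge(frame.residues, resolution, b)
        expected = recipe.targets[b.name]
        if ends & altloc_positions:
            # the winning conformer decides; designed coords win only for
            # occ A >= occ B, otherwise the displaced conformer is in play
            dup = next(al for al in recipe.altlocs if al.author_position in ends)
            if dup.occupancies[0] < dup.occupancies[1]:
                continue
        if not m.measurable or abs(m.min_distance - expected) > 0.02:
            got = "unmeasurable" if not m.measurable else f"{m.min_distance:.3f}"
            raise GenerationError(
                f"{recipe.name}: bridge {b.name} designed {expected:.3f} Å, got {got}"
            )


# --------------------------------------------------------------------------
# the canonical suite


@dataclass(frozen=True)
class SuiteEntry:
    recipe: FixtureRecipe
    expected_state: str


def suite_recipes(config: Config, seed: int = 0) -> List[SuiteEntry]:
    """Canonical fixture suite covering both numbering offsets, all call
    states, altloc ties, missing side chains and marker-residue mutants."""
    cutoff = config.bridges[0].cutoff
    entries: List[SuiteEntry] = []
    k = 0

    def add(expected: str, **kw) -> None:
        nonlocal k
        entries.append(SuiteEntry(FixtureRecipe(seed=seed + k, **kw), expected))
        k += 1

    for off in (0, -18):
        tag = "iso" if off == 0 else "pdb"
        add("inactive", name=f"syn_{tag}_inactive", numbering_offset=off,
            targets={"HD": 3.5, "KE": 9.0})
        add("active", name=f"syn_{tag}_active", numbering_offset=off,
            targets={"HD": 8.0, "KE": 3.2})
        add("conflict", name=f"syn_{tag}_conflict", numbering_offset=off,
            targets={"HD": 3.5, "KE": 3.5})
        add("indeterminate", name=f"syn_{tag}_indeterminate", numbering_offset=off,
            targets={"HD": 8.0, "KE": 9.0})
        add("excluded_non_wildtype", name=f"syn_{tag}_mutant_i1102t",
            numbering_offset=off, targets={"HD": 3.5, "KE": 9.0},
            mutations={1102 + off: "THR"})

    # marker-quartet mutant: catalytic Lys replaced
    add("excluded_non_wildtype", name="syn_iso_mutant_k1128m",
        targets={"HD": 3.5, "KE": 9.0}, mutations={1128: "MET"})
    # disordered acceptor side chain: bridge distance unknowable
    add("unmeasurable", name="syn_iso_dropped_d1151",
        targets={"HD": 3.5, "KE": 9.0}, drop_side_chains=(1151,))
    # altloc tie on the His donor: first conformer (designed) must win
    add("inactive", name="syn_iso_altloc_tie",
        targets={"HD": 3.5, "KE": 9.0},
        altlocs=(AltlocDuplicate(1086, "NE2", (0.5, 0.5)),))
    # higher-occupancy first conformer wins outright
    add("inactive", name="syn_iso_altloc_majority",
        targets={"HD": 3.5, "KE": 9.0},
        altlocs=(AltlocDuplicate(1086, "NE2", (0.7, 0.3)),))
    # threshold bracketing around the salt-bridge cutoff
    add("inactive", name="syn_iso_bracket_below",
        targets={"HD": round(cutoff - 0.05, 2), "KE": 9.0})
    add("indeterminate", name="syn_iso_bracket_above",
        targets={"HD": round(cutoff + 0.05, 2), "KE": 9.0})
    # chain selection: first chain lacks the bridge residues
    add("inactive", name="syn_iso_second_chain",
        targets={"HD": 3.5, "KE": 9.0}, incomplete_first_chain=True)
    # model policy: only model 1 is measured
    add("inactive", name="syn_iso_two_models",
        targets={"HD": 3.5, "KE": 9.0}, extra_model=True)
    # no offset can reconcile identities
    scrambled = [(p, "LEU") for p in
                 [s.paper_position for s in config.residue_specs]]
    add("excluded_unresolved", name="syn_iso_scrambled",
        targets={}, plan=scrambled)
    return entries


TRUTH_COLUMNS = ("name", "expected_state", "offset", "target_HD_A", "target_KE_A")


def fixture_suite(
    config: Config, out_dir: str, seed: int = 0, formats: Sequence[str] = ("pdb", "mmcif"),
) -> List[Tuple[str, SuiteEntry]]:
    """Write the canonical suite (PDB + mmCIF mirrors) plus a truth table.

    Returns (structure path, suite entry) pairs, PDB paths first.
    """
    os.makedirs(out_dir, exist_ok=True)
    written: List[Tuple[str, SuiteEntry]] = []
    rows = ["\t".join(TRUTH_COLUMNS)]
    for entry in suite_recipes(config, seed=seed):
        sm = build_fixture(entry.recipe, config)
        base = os.path.join(out_dir, entry.recipe.name)
        if "pdb" in formats:
            write_pdb(sm, base + ".pdb")
            written.append((base + ".pdb", entry))
        if "mmcif" in formats:
            write_mmcif(sm, base + ".cif")
            written.append((base + ".cif", entry))
        t = entry.recipe.targets
        rows.append("\t".join([
            entry.recipe.name, entry.expected_state,
            str(entry.recipe.numbering_offset),
            f"{t.get('HD', float('nan')):.2f}" if "HD" in t else "NA",
            f"{t.get('KE', float('nan')):.2f}" if "KE" in t else "NA",
        ]))
    with open(os.path.join(out_dir, "truth.tsv"), "w") as fh:
        fh.write("\n".join(rows) + "\n")
    return written
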