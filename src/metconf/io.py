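"""Reading and writing macromolecular coordinate files.

Parsing is delegated to gemmi (PDB and mmCIF); the parsed tree is converted
into the light-weight :class:`~metconf.model.StructureModel` the rest of the
pipeline consumes.  Waters are stripped at parse time; other heteroatom
groups (ATP, inhibitors, ions) survive as flagged groups so that ligands are
never silently dropped.  Hydrogens are kept in the model but excluded from
all distance work downstream.

Writing is done by small in-package emitters (fixed-width PDB, minimal
mmCIF ``atom_site`` loop) so that synthetic fixtures control column
precision and altloc order exactly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import gemmi

from .model import (
    AA3_TO_1,
    AtomRecord,
    ChainMap,
    EmptyStructureError,
    Frame,
    ResidueRecord,
    SelectionError,
    StructureModel,
    StructureParseError,
    WATER_NAMES,
    resolve_altlocs,
)

_PDB_EXT = {".pdb", ".ent", ".pdb1"}
_CIF_EXT = {".cif", ".mmcif"}

# HETATM residue names that are nevertheless polymer components.
_POLYMER_HET = {"MSE", "SEP", "TPO", "PTR"}


def _detect_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    if ext in _PDB_EXT:
        return "pdb"
    if ext in _CIF_EXT:
        return "mmcif"
    # sniff: mmCIF files start with data_ blocks / category lines
    try:
        with open(path, "r", errors="replace") as fh:
            head = fh.read(4096)
    except OSError as exc:
        raise StructureParseError(f"cannot read {path}: {exc}") from exc
    if "data_" in head or "_atom_site" in head:
        return "mmcif"
    return "pdb"


def _is_polymer_residue(res: gemmi.Residue) -> bool:
    if res.name in WATER_NAMES:
        return False
    if res.name in AA3_TO_1 or res.name in _POLYMER_HET:
        return True
    # unknown residue written as ATOM records: trust the deposition
    return res.het_flag == "A"


def read_structure(path: str, format: Optional[str] = None) -> StructureModel:
    """Parse a PDB or mmCIF file into a :class:`StructureModel`.

    Waters are excluded.  Non-polymer heteroatom groups are retained with
    ``is_hetero=True``.  Raises :class:`StructureParseError` on unreadable
    input and :class:`EmptyStructureError` when no polymer atoms remain.
    """
    if not os.path.exists(path):
        raise StructureParseError(f"no such file: {path}")
    fmt = format or _detect_format(path)
    if fmt not in ("pdb", "mmcif"):
        raise StructureParseError(f"unknown format {fmt!r} for {path}")
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(path)
        else:
            st = gemmi.read_structure(path, format=gemmi.CoorFormat.Mmcif)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"failed to parse {path} as {fmt}: {exc}") from exc

    entry_id = st.name.strip() or os.path.splitext(os.path.basename(path))[0]
    models: List[ChainMap] = []
    for model in st:
        chains: ChainMap = {}
        for chain in model:
            residues: List[ResidueRecord] = []
            for res in chain:
                if res.name in WATER_NAMES:
                    continue
                is_het = not _is_polymer_residue(res)
                atoms = [
                    AtomRecord(
                        name=atom.name,
                        element=atom.element.name.upper(),
                        coords=(atom.pos.x, atom.pos.y, atom.pos.z),
                        altloc=atom.altloc if atom.altloc != "\x00" else "",
                        occupancy=min(max(atom.occ, 0.0), 1.0),
                    )
                    for atom in res
                ]
                if not atoms:
                    continue
                icode = res.seqid.icode.strip()
                residues.append(
                    ResidueRecord(res.seqid.num, icode, res.name, atoms, is_het)
                )
            if residues:
                chains[chain.name] = residues
        if chains:
            models.append(chains)

    if not models:
        raise EmptyStructureError(f"{path}: no coordinate records found")
    sm = StructureModel(entry_id=entry_id, models=models, source_format=fmt)
    if sm.atom_count(polymer_only=True) == 0:
        raise EmptyStructureError(f"{path}: no polymer atoms")
    return sm


# ---------------------------------------------------------------------------
# frame selection


def select_frame(
    s: StructureModel,
    model_index: int = 1,
    chain_id: Optional[str] = None,
    required_position_sets: Optional[Sequence[Set[int]]] = None,
) -> Frame:
    """Pick one model and one chain and resolve altlocs.

    ``required_position_sets`` holds one author-number set per candidate
    numbering offset; a chain qualifies when it covers at least one full
    set (at empty insertion code).  Without constraints, the first chain in
    file order is used.  Altloc policy: highest occupancy wins, ties broken
    by file order.
    """
    if not 1 <= model_index <= len(s.models):
        raise SelectionError(
            f"{s.entry_id}: model {model_index} out of range (1..{len(s.models)})"
        )
    chains = s.models[model_index - 1]

    if chain_id is not None:
        if chain_id not in chains:
            raise SelectionError(
                f"{s.entry_id}: chain {chain_id!r} not present "
                f"(available: {', '.join(chains)})"
            )
        chosen = chain_id
    elif not required_position_sets:
        chosen = next(iter(chains))
    else:
        chosen = ""
        missing_report: Dict[str, List[int]] = {}
        for cid, residues in chains.items():
            numbers = {
                r.author_number for r in residues
                if not r.is_hetero and r.insertion_code == ""
            }
            best_missing: Optional[List[int]] = None
            for wanted in required_position_sets:
                missing = sorted(set(wanted) - numbers)
                if not missing:
                    chosen = cid
                    break
                if best_missing is None or len(missing) < len(best_missing):
                    best_missing = missing
            if chosen:
                break
            missing_report[cid] = best_missing or []
        if not chosen:
            detail = "; ".join(
                f"chain {cid} missing {miss}" for cid, miss in missing_report.items()
            )
            raise SelectionError(
                f"{s.entry_id}: no chain contains all required positions ({detail})"
            )

    polymer = [resolve_altlocs(r) for r in chains[chosen] if not r.is_hetero]
    hetero = [resolve_altlocs(r) for r in chains[chosen] if r.is_hetero]
    return Frame(
        entry_id=s.entry_id,
        model_index=model_index,
        chain_id=chosen,
        residues=polymer,
        hetero=hetero,
    )


# ---------------------------------------------------------------------------
# sequence extraction


@dataclass
class ChainSequence:
    """Author-numbered one-letter sequence of one chain."""

    mapping: Dict[int, str] = field(default_factory=dict)

    @property
    def absent_positions(self) -> List[int]:
        """Author numbers missing between the observed min and max."""
        if not self.mapping:
            return []
        lo, hi = min(self.mapping), max(self.mapping)
        return [i for i in range(lo, hi + 1) if i not in self.mapping]

    def one_letter(self) -> str:
        return "".join(self.mapping[k] for k in sorted(self.mapping))


def chain_sequence(residues: Sequence[ResidueRecord]) -> ChainSequence:
    """One-letter sequence indexed by author number (empty icode only).

    Nonstandard residues become ``"X"``; numbering gaps are preserved as
    missing keys, never padded.
    """
    mapping: Dict[int, str] = {}
    for r in residues:
        if r.is_hetero or r.insertion_code != "":
            continue
        mapping[r.author_number] = r.aa1
    return ChainSequence(mapping)


# ---------------------------------------------------------------------------
# writers


def _pdb_atom_name(name: str, element: str) -> str:
    # standard alignment: 1-char elements start in column 14
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_pdb(s: StructureModel, path: str) -> None:
    """Write the model as fixed-width PDB (8.3 coordinate columns)."""
    lines: List[str] = []
    multi = len(s.models) > 1
    serial = 0
    for mi, chains in enumerate(s.models, start=1):
        if multi:
            lines.append(f"MODEL     {mi:4d}")
        for cid, residues in chains.items():
            for res in residues:
                record = "HETATM" if res.is_hetero else "ATOM  "
                for atom in res.atoms:
                    serial += 1
                    name = _pdb_atom_name(atom.name, atom.element)
                    alt = atom.altloc or " "
                    icode = res.insertion_code or " "
                    x, y, z = atom.coords
                    lines.append(
                        f"{record}{serial % 100000:5d} {name}{alt}{res.aa3:>3s} "
                        f"{cid[:1]}{res.author_number:4d}{icode}   "
                        f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                        f"          {atom.element:>2s}"
                    )
            if residues and not residues[-1].is_hetero:
                serial += 1
                last = residues[-1]
                lines.append(
                    f"TER   {serial % 100000:5d}      {last.aa3:>3s} "
                    f"{cid[:1]}{last.author_number:4d}{last.insertion_code or ' '}"
                )
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


_CIF_HEADER = """\
loop_
_atom_site.group_PDB
_atom_site.id
_atom_site.type_symbol
_atom_site.label_atom_id
_atom_site.label_alt_id
_atom_site.label_comp_id
_atom_site.label_asym_id
_atom_site.label_entity_id
_atom_site.label_seq_id
_atom_site.pdbx_PDB_ins_code
_atom_site.Cartn_x
_atom_site.Cartn_y
_atom_site.Cartn_z
_atom_site.occupancy
_atom_site.B_iso_or_equiv
_atom_site.auth_seq_id
_atom_site.auth_asym_id
_atom_site.pdbx_PDB_model_num
"""


def write_mmcif(s: StructureModel, path: str) -> None:
    """Write the model as a minimal mmCIF ``atom_site`` loop."""
    rows: List[str] = []
    serial = 0
    for mi, chains in enumerate(s.models, start=1):
        for cid, residues in chains.items():
            for res in residues:
                group = "HETATM" if res.is_hetero else "ATOM"
                icode = res.insertion_code or "?"
                for atom in res.atoms:
                    serial += 1
                    alt = atom.altloc or "."
                    x, y, z = atom.coords
                    rows.append(
                        f"{group} {serial} {atom.element} {atom.name} {alt} "
                        f"{res.aa3} {cid} 1 {res.author_number} {icode} "
                        f"{x:.3f} {y:.3f} {z:.3f} {atom.occupancy:.2f} 0.00 "
                        f"{res.author_number} {cid} {mi}"
                    )
    block = f"data_{s.entry_id}\n#\n" + _CIF_HEADER + "\n".join(rows) + "\n#\n"
    with open(path, "w") as fh:
        fh.write(block)
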