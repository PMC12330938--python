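"""Core coordinate model shared by every stage of the pipeline.

A parsed structure is a small tree: ``StructureModel`` → models → chains →
``ResidueRecord`` → ``AtomRecord``.  Author numbering (the residue numbers
printed in the deposited file) is kept verbatim; nothing is renumbered at
parse time.  Alternate locations are preserved in file order and resolved
only when a single frame is selected for measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np

# Standard three-letter -> one-letter translation.  Anything else maps to "X".
AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

#: One-letter codes of residues with polar/charged side chains, as used by
#: the polar-neighbour scan around the ATP-site entrance.
POLAR_AA1 = frozenset("DEKRHNQSTY")

#: Backbone heavy atoms excluded from side-chain distance work.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})


class StructureError(Exception):
    """Base class for structure-layer failures."""


class StructureParseError(StructureError):
    """File could not be parsed as PDB or mmCIF."""


class EmptyStructureError(StructureError):
    """File parsed but contained no polymer atoms."""


class SelectionError(StructureError):
    """No model/chain satisfied the selection constraints."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom site: name, element, Cartesian coordinates in Å."""

    name: str
    element: str
    coords: Tuple[float, float, float]
    altloc: str = ""
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("atom name must be nonempty")
        if not all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(
                f"occupancy {self.occupancy} outside [0, 1] for atom {self.name}"
            )

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coords, dtype=float)

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class ResidueRecord:
    """One residue (or flagged non-polymer group) with its atoms."""

    author_number: int
    insertion_code: str
    aa3: str
    atoms: List[AtomRecord] = field(default_factory=list)
    is_hetero: bool = False  # non-polymer group (e.g. ATP); never a water

    def __post_init__(self) -> None:
        self.aa3 = self.aa3.upper()

    @property
    def aa1(self) -> str:
        return AA3_TO_1.get(self.aa3, "X")

    def heavy_atoms(self, altloc_resolved: bool = False) -> List[AtomRecord]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def side_chain_atoms(self) -> List[AtomRecord]:
        return [
            a for a in self.atoms
            if not a.is_hydrogen and a.name not in BACKBONE_ATOMS
        ]

    def atoms_named(self, names: Iterable[str]) -> List[AtomRecord]:
        wanted = set(names)
        return [a for a in self.atoms if a.name in wanted and not a.is_hydrogen]

    def key(self) -> Tuple[int, str]:
        return (self.author_number, self.insertion_code)


# One model: ordered mapping chain id -> ordered residue list.
ChainMap = Dict[str, List[ResidueRecord]]


@dataclass
class StructureModel:
    """Parsed structure: ordered models, each a chain -> residue-list map."""

    entry_id: str
    models: List[ChainMap]
    source_format: str  # "pdb" | "mmcif" | "memory"

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("StructureModel requires at least one model")

    def n_models(self) -> int:
        return len(self.models)

    def chain_ids(self, model_index: int = 1) -> List[str]:
        return list(self.models[model_index - 1].keys())

    def polymer_residues(self, model_index: int = 1, chain_id: str = "") -> List[ResidueRecord]:
        chain = self.models[model_index - 1][chain_id]
        return [r for r in chain if not r.is_hetero]

    def hetero_groups(self, model_index: int = 1) -> List[Tuple[str, ResidueRecord]]:
        """All flagged non-polymer groups of one model as (chain_id, residue)."""
        out = []
        for cid, residues in self.models[model_index - 1].items():
            out.extend((cid, r) for r in residues if r.is_hetero)
        return out

    def atom_count(self, polymer_only: bool = False) -> int:
        n = 0
        for chains in self.models:
            for residues in chains.values():
                for r in residues:
                    if polymer_only and r.is_hetero:
                        continue
                    n += len(r.atoms)
        return n

    def residue_count(self, polymer_only: bool = False) -> int:
        n = 0
        for chains in self.models:
            for residues in chains.values():
                n += sum(1 for r in residues if not (polymer_only and r.is_hetero))
        return n


def resolve_altlocs(residue: ResidueRecord) -> ResidueRecord:
    """Collapse alternate locations to a single conformer.

    Policy: per atom name, keep the altloc with highest occupancy; ties are
    broken by file order (first wins).  Atoms without altloc are untouched.
    """
    best: Dict[str, AtomRecord] = {}
    order: List[str] = []
    for atom in residue.atoms:
        if atom.name not in best:
            best[atom.name] = atom
            order.append(atom.name)
        elif atom.occupancy > best[atom.name].occupancy:
            best[atom.name] = atom
    # keep winners in first-appearance order, stripping the altloc marker
    resolved = [
        AtomRecord(a.name, a.element, a.coords, "", a.occupancy)
        for a in (best[name] for name in order)
    ]
    return ResidueRecord(
        residue.author_number, residue.insertion_code, residue.aa3,
        resolved, residue.is_hetero,
    )


@dataclass
class Frame:
    """A single measurable view: one model, one chain, altlocs resolved."""

    entry_id: str
    model_index: int
    chain_id: str
    residues: List[ResidueRecord]
    hetero: List[ResidueRecord] = field(default_factory=list)

    def residue_at(self, author_number: int, insertion_code: str = "") -> Optional[ResidueRecord]:
        for r in self.residues:
            if r.author_number == author_number and r.insertion_code == insertion_code:
                return r
        return None

    def author_numbers(self) -> List[int]:
        return [r.author_number for r in self.residues if r.insertion_code == ""]
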