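"""Salt-bridge, hydrophobic-contact and polar-neighbour measurements.

A salt bridge is operationalized the classic way: the minimum distance over
the grid of basic side-chain nitrogens × acidic carboxylate oxygens, called
present when it does not exceed a cutoff (default 4.0 Å).  His donates via
{ND1, NE2}, Lys via {NZ}; Asp accepts via {OD1, OD2}, Glu via {OE1, OE2}.
Reporting the full pair grid (not just the minimum) lets a user locate any
single printed literature distance among the chemically equivalent atoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .model import POLAR_AA1, ResidueRecord
from .numbering import NumberingResolution, ResidueSpec

#: Conventional donor/acceptor side-chain atom sets per one-letter code.
DONOR_ATOMS = {"H": ("ND1", "NE2"), "K": ("NZ",), "R": ("NE", "NH1", "NH2")}
ACCEPTOR_ATOMS = {"D": ("OD1", "OD2"), "E": ("OE1", "OE2")}

DEFAULT_SALT_BRIDGE_CUTOFF = 4.0
DEFAULT_CONTACT_CUTOFF = 4.5


@dataclass(frozen=True)
class BridgeEnd:
    """One end of a salt bridge: marker residue plus its bridging atoms."""

    spec: ResidueSpec
    atoms: Tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"empty atom set for position {self.spec.paper_position}")


@dataclass(frozen=True)
class SaltBridgeSpec:
    name: str
    donor: BridgeEnd
    acceptor: BridgeEnd
    cutoff: float = DEFAULT_SALT_BRIDGE_CUTOFF

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError(f"bridge {self.name}: cutoff must be positive")


@dataclass(frozen=True)
class ContactSpec:
    """Side-chain heavy-atom contact between two marker residues."""

    a: ResidueSpec
    b: ResidueSpec
    cutoff: float = DEFAULT_CONTACT_CUTOFF

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("contact cutoff must be positive")


@dataclass
class BridgeMeasurement:
    bridge_name: str
    measurable: bool
    min_distance: Optional[float] = None
    min_pair: Optional[Tuple[str, str]] = None
    all_pairs: Dict[Tuple[str, str], float] = field(default_factory=dict)
    present: bool = False
    cutoff: float = DEFAULT_SALT_BRIDGE_CUTOFF

    def to_dict(self) -> dict:
        return {
            "bridge": self.bridge_name,
            "measurable": self.measurable,
            "min_distance": None if self.min_distance is None else round(self.min_distance, 2),
            "min_pair": self.min_pair,
            "present": self.present,
            "cutoff": self.cutoff,
            "all_pairs": {
                f"{d}-{a}": round(v, 2) for (d, a), v in sorted(self.all_pairs.items())
            },
        }


def _pair_distances(
    donor_atoms: Sequence, acceptor_atoms: Sequence
) -> Dict[Tuple[str, str], float]:
    if not donor_atoms or not acceptor_atoms:
        return {}
    dxyz = np.stack([a.xyz for a in donor_atoms])
    axyz = np.stack([a.xyz for a in acceptor_atoms])
    dist = np.linalg.norm(dxyz[:, None, :] - axyz[None, :, :], axis=-1)
    return {
        (donor_atoms[i].name, acceptor_atoms[j].name): float(dist[i, j])
        for i in range(len(donor_atoms))
        for j in range(len(acceptor_atoms))
    }


def _find(
    residues: Sequence[ResidueRecord], resolution: NumberingResolution, paper_position: int
) -> Optional[ResidueRecord]:
    author = resolution.author_number(paper_position)
    for r in residues:
        if (
            not r.is_hetero
            and r.insertion_code == ""
            and r.author_number == author
        ):
            return r
    return None


def measure_bridge(
    residues: Sequence[ResidueRecord],
    resolution: NumberingResolution,
    spec: SaltBridgeSpec,
) -> BridgeMeasurement:
    """Minimum donor–acceptor heavy-atom distance for one salt bridge.

    Returns an unmeasurable result (no distances, ``present=False``) when
    either residue is absent or lacks every listed bridging atom.
    """
    donor_res = _find(residues, resolution, spec.donor.spec.paper_position)
    acceptor_res = _find(residues, resolution, spec.acceptor.spec.paper_position)
    donor_atoms = donor_res.atoms_named(spec.donor.atoms) if donor_res else []
    acceptor_atoms = acceptor_res.atoms_named(spec.acceptor.atoms) if acceptor_res else []
    pairs = _pair_distances(donor_atoms, acceptor_atoms)
    if not pairs:
        return BridgeMeasurement(spec.name, measurable=False, cutoff=spec.cutoff)
    min_pair = min(pairs, key=pairs.get)
    min_distance = pairs[min_pair]
    return BridgeMeasurement(
        bridge_name=spec.name,
        measurable=True,
        min_distance=min_distance,
        min_pair=min_pair,
        all_pairs=pairs,
        present=min_distance <= spec.cutoff,
        cutoff=spec.cutoff,
    )


@dataclass
class ContactMeasurement:
    name: str
    measurable: bool
    min_distance: Optional[float] = None
    min_pair: Optional[Tuple[str, str]] = None
    present: bool = False


def measure_contact(
    residues: Sequence[ResidueRecord],
    resolution: NumberingResolution,
    spec: ContactSpec,
) -> ContactMeasurement:
    """Minimum side-chain heavy-atom distance between two marker residues."""
    name = f"{spec.a.expected_aa}{spec.a.paper_position}/{spec.b.expected_aa}{spec.b.paper_position}"
    res_a = _find(residues, resolution, spec.a.paper_position)
    res_b = _find(residues, resolution, spec.b.paper_position)
    atoms_a = res_a.side_chain_atoms() if res_a else []
    atoms_b = res_b.side_chain_atoms() if res_b else []
    pairs = _pair_distances(atoms_a, atoms_b)
    if not pairs:
        return ContactMeasurement(name, measurable=False)
    min_pair = min(pairs, key=pairs.get)
    d = pairs[min_pair]
    return ContactMeasurement(name, True, d, min_pair, d <= spec.cutoff)


@dataclass
class PolarNeighbor:
    paper_position: int
    author_number: int
    aa1: str
    min_distance: float


def polar_neighbor_scan(
    residues: Sequence[ResidueRecord],
    resolution: NumberingResolution,
    center: int,
    radius: float,
) -> Optional[List[PolarNeighbor]]:
    """Polar residues whose side chain approaches the center's side chain.

    ``center`` is an isoform position; returns neighbours with minimum
    side-chain heavy-atom distance ≤ radius, sorted by distance, or None
    when the center residue (or its side chain) is not observed.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    center_res = _find(residues, resolution, center)
    if center_res is None:
        return None
    center_atoms = center_res.side_chain_atoms()
    if not center_atoms:
        return None
    cxyz = np.stack([a.xyz for a in center_atoms])
    offset = resolution.offset or 0
    out: List[PolarNeighbor] = []
    for r in residues:
        if r.is_hetero or r.insertion_code != "" or r is center_res:
            continue
        if r.aa1 not in POLAR_AA1:
            continue
        atoms = r.side_chain_atoms()
        if not atoms:
            continue
        xyz = np.stack([a.xyz for a in atoms])
        d = float(np.min(np.linalg.norm(cxyz[:, None, :] - xyz[None, :, :], axis=-1)))
        if d <= radius:
            out.append(PolarNeighbor(r.author_number - offset, r.author_number, r.aa1, d))
    out.sort(key=lambda n: n.min_distance)
    return out
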