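"""Reconciling isoform numbering with author numbering.

MET residues are quoted in the literature in two schemes that differ by 18
residues: the long-isoform numbering (transcript variant 1, catalytic
lysine K1128, DFG aspartate D1240) and the short-isoform numbering most PDB
depositions use (K1110, D1222).  Rather than aligning sequences, the
resolver tries a small list of candidate offsets (default ``[0, -18]``,
author = isoform + offset) and accepts the unique offset under which every
configured marker residue present in the chain carries its expected
identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .model import AA1_TO_3, Frame, ResidueRecord

DEFAULT_CANDIDATE_OFFSETS = (0, -18)


@dataclass(frozen=True)
class ResidueSpec:
    """A marker residue in isoform (paper-style) numbering."""

    paper_position: int
    expected_aa: str  # one-letter
    label: str = ""

    def __post_init__(self) -> None:
        if self.paper_position <= 0:
            raise ValueError(f"paper_position must be positive, got {self.paper_position}")
        if self.expected_aa not in AA1_TO_3:
            raise ValueError(f"expected_aa {self.expected_aa!r} is not a standard amino acid")


@dataclass
class NumberingResolution:
    """Outcome of offset resolution for one chain."""

    status: str  # "resolved" | "ambiguous" | "failed"
    offset: Optional[int] = None
    verified_positions: List[Tuple[int, int, str]] = field(default_factory=list)
    candidate_matches: Dict[int, Tuple[int, int]] = field(default_factory=dict)
    # candidate_matches: offset -> (n specs present, n matching)

    @property
    def resolved(self) -> bool:
        return self.status == "resolved"

    def author_number(self, paper_position: int) -> int:
        if not self.resolved:
            raise ValueError("numbering not resolved")
        assert self.offset is not None
        return paper_position + self.offset


def _residue_index(residues: Sequence[ResidueRecord]) -> Dict[int, ResidueRecord]:
    return {
        r.author_number: r
        for r in residues
        if not r.is_hetero and r.insertion_code == ""
    }


def resolve_numbering(
    residues: Sequence[ResidueRecord],
    specs: Sequence[ResidueSpec],
    candidate_offsets: Iterable[int] = DEFAULT_CANDIDATE_OFFSETS,
) -> NumberingResolution:
    """Find the unique offset mapping isoform positions onto this chain.

    For each candidate offset the mapped position of every spec is looked
    up; an offset is a *full match* when at least one spec position exists
    in the chain and every one that exists carries the expected identity.
    Exactly one full match → resolved; more → ambiguous; none → a
    near-match fallback.

    The fallback exists because a structure carrying a single point
    mutation at a marker position must still be numberable — otherwise it
    could never be reported as non-wild-type, only as unresolvable.  When
    no offset matches perfectly, a unique offset matching at least 75% of
    its present markers (and at least three of them) is accepted; the
    wild-type filter then reports the mismatching positions.
    """
    if not specs:
        raise ValueError("resolve_numbering requires at least one ResidueSpec")
    index = _residue_index(residues)
    full_matches: List[int] = []
    candidate_matches: Dict[int, Tuple[int, int]] = {}
    details: Dict[int, List[Tuple[int, int, str]]] = {}
    for offset in candidate_offsets:
        present = 0
        matching = 0
        verified: List[Tuple[int, int, str]] = []
        for spec in specs:
            author = spec.paper_position + offset
            res = index.get(author)
            if res is None:
                continue
            present += 1
            if res.aa1 == spec.expected_aa:
                matching += 1
                verified.append((spec.paper_position, author, res.aa1))
        candidate_matches[offset] = (present, matching)
        details[offset] = verified
        if present > 0 and matching == present:
            full_matches.append(offset)

    if len(full_matches) == 1:
        off = full_matches[0]
        return NumberingResolution(
            status="resolved",
            offset=off,
            verified_positions=details[off],
            candidate_matches=candidate_matches,
        )
    if len(full_matches) > 1:
        return NumberingResolution(status="ambiguous", candidate_matches=candidate_matches)

    near = [
        off for off, (present, matching) in candidate_matches.items()
        if present > 0 and matching >= 3 and matching / present >= 0.75
    ]
    if len(near) == 1:
        off = near[0]
        return NumberingResolution(
            status="resolved",
            offset=off,
            verified_positions=details[off],
            candidate_matches=candidate_matches,
        )
    if len(near) > 1:
        return NumberingResolution(status="ambiguous", candidate_matches=candidate_matches)
    return NumberingResolution(status="failed", candidate_matches=candidate_matches)


@dataclass
class WildtypeReport:
    """Per-position identity report against the configured markers."""

    passed: bool
    positions: Dict[int, str] = field(default_factory=dict)
    # paper position -> "match" | "mismatch" | "unobserved" | "atoms-missing"
    failing_positions: List[int] = field(default_factory=list)
    reason: str = ""


def wildtype_filter(
    residues: Sequence[ResidueRecord],
    resolution: NumberingResolution,
    specs: Sequence[ResidueSpec],
    bridge_positions: Optional[Dict[int, Sequence[str]]] = None,
) -> WildtypeReport:
    """Check that every marker position present carries its wild-type residue.

    ``bridge_positions`` maps bridge-defining isoform positions to the atom
    names a measurement needs; an unobserved bridge position, or one whose
    listed atoms are all missing (disordered side chain), makes the
    structure unmeasurable — which is a failure distinct from a mutation.
    """
    if not resolution.resolved:
        raise ValueError("wildtype_filter requires resolved numbering")
    index = _residue_index(residues)
    bridge_positions = bridge_positions or {}

    positions: Dict[int, str] = {}
    mismatches: List[int] = []
    unmeasurable: List[int] = []
    for spec in specs:
        author = resolution.author_number(spec.paper_position)
        res = index.get(author)
        needed_atoms = bridge_positions.get(spec.paper_position)
        if res is None:
            positions[spec.paper_position] = "unobserved"
            if needed_atoms is not None:
                unmeasurable.append(spec.paper_position)
            continue
        if res.aa1 != spec.expected_aa:
            positions[spec.paper_position] = "mismatch"
            mismatches.append(spec.paper_position)
            continue
        if needed_atoms is not None and not res.atoms_named(needed_atoms):
            positions[spec.paper_position] = "atoms-missing"
            unmeasurable.append(spec.paper_position)
            continue
        positions[spec.paper_position] = "match"

    if mismatches:
        return WildtypeReport(
            passed=False,
            positions=positions,
            failing_positions=sorted(mismatches),
            reason="non-wildtype",
        )
    if unmeasurable:
        return WildtypeReport(
            passed=False,
            positions=positions,
            failing_positions=sorted(unmeasurable),
            reason="unmeasurable",
        )
    return WildtypeReport(passed=True, positions=positions)
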