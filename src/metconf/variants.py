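"""HGVS protein-variant parsing and MET domain annotation.

Positions are interpreted in long-isoform numbering (transcript variant 1,
NM_001127500.1), the scheme clinical reports use for MET; it runs 18
residues ahead of the short-isoform numbering of most structural papers.
The domain map is configuration, not code: boundaries ship in the default
YAML and are validated against the clinically annotated variant set and the
kinase sub-element anchors (αJM-helix ending at H1086, β1 holding I1102,
hinge holding P1176/M1178, DFG at D1240, C-lobe holding M1268).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

from .model import AA1_TO_3, AA3_TO_1

OUTSIDE_DOMAINS = "outside annotated domains"

#: The ten uncharacterized germline/somatic MET variants reported from
#: HPRCC and NSCLC screening, as printed (one row carries only a position).
MET_VARIANT_PANEL = (
    "p.(Val37Ala)",
    "p.(Arg426Pro)",
    "p.(Ser1018Pro)",
    "p.(Gly1056Glu)",
    "I1102",
    "p.(Ile1102Thr)",
    "p.(Cys1125Gly)",
    "p.(Leu1130Ser)",
    "p.(His1097Arg)",
    "p.(Asp1249Glu)",
)


class HgvsParseError(ValueError):
    """Raised for malformed HGVS protein substitution strings."""


@dataclass(frozen=True)
class ProteinVariant:
    """A protein substitution; ``alt_aa`` is None for position-only tokens."""

    ref_aa: str
    position: int
    alt_aa: Optional[str]
    raw: str

    def __post_init__(self) -> None:
        if self.position <= 0:
            raise ValueError(f"position must be positive in {self.raw!r}")
        if self.alt_aa is not None and self.ref_aa == self.alt_aa:
            raise ValueError(f"silent substitution in {self.raw!r}")

    def hgvs(self) -> str:
        if self.alt_aa is None:
            return f"{self.ref_aa}{self.position}"
        ref3 = AA1_TO_3[self.ref_aa].capitalize()
        alt3 = AA1_TO_3[self.alt_aa].capitalize()
        return f"p.({ref3}{self.position}{alt3})"


_HGVS_RE = re.compile(r"^p\.\(?([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2})\)?$")
_SHORT_RE = re.compile(r"^([A-Z])(\d+)([A-Z])?$")


def _aa3_to_1(token: str, raw: str) -> str:
    aa = AA3_TO_1.get(token.upper())
    if aa is None:
        raise HgvsParseError(f"unknown residue code {token!r} in {raw!r}")
    return aa


def parse_hgvs_p(s: str) -> ProteinVariant:
    """Parse a strict HGVS protein substitution, e.g. ``p.(Ile1102Thr)``."""
    token = s.strip()
    m = _HGVS_RE.match(token)
    if not m:
        raise HgvsParseError(f"not an HGVS protein substitution: {s!r}")
    ref = _aa3_to_1(m.group(1), s)
    alt = _aa3_to_1(m.group(3), s)
    if ref == alt:
        raise HgvsParseError(f"silent substitution {s!r}")
    return ProteinVariant(ref, int(m.group(2)), alt, s)


def parse_variant_token(s: str) -> ProteinVariant:
    """Lenient parse: HGVS, one-letter shorthand (I1102T), or position-only
    shorthand (I1102, substitution left unspecified)."""
    token = s.strip()
    if not token:
        raise HgvsParseError("empty variant string")
    try:
        return parse_hgvs_p(token)
    except HgvsParseError:
        pass
    m = _SHORT_RE.match(token)
    if m and m.group(1) in AA1_TO_3 and (m.group(3) is None or m.group(3) in AA1_TO_3):
        ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
        if alt is not None and alt == ref:
            raise HgvsParseError(f"silent substitution {s!r}")
        return ProteinVariant(ref, pos, alt, s)
    raise HgvsParseError(f"unparseable variant token: {s!r}")


@dataclass(frozen=True)
class DomainInterval:
    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.name}: start {self.start} > end {self.end}")

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass
class DomainMap:
    """Two-tier map: protein domains, plus sub-elements inside one domain."""

    domains: List[DomainInterval]
    sub_elements: List[DomainInterval] = field(default_factory=list)
    sub_element_domain: str = "Kinase domain"

    def __post_init__(self) -> None:
        for tier in (self.domains, self.sub_elements):
            ordered = sorted(tier, key=lambda d: d.start)
            for a, b in zip(ordered, ordered[1:]):
                if b.start <= a.end:
                    raise ValueError(f"overlapping intervals: {a.name} / {b.name}")

    def domain_of(self, position: int) -> str:
        for d in self.domains:
            if position in d:
                return d.name
        return OUTSIDE_DOMAINS

    def sub_element_of(self, position: int) -> Optional[str]:
        if self.domain_of(position) != self.sub_element_domain:
            return None
        for s in self.sub_elements:
            if position in s:
                return s.name
        return None


@dataclass
class AnnotationResult:
    variant: Optional[ProteinVariant]
    domain: str
    sub_element: Optional[str] = None
    notes: str = ""
    raw: str = ""
    error: Optional[str] = None

    @property
    def ok(self) -> bool:
        return self.error is None


def assign_domain(v: ProteinVariant, m: DomainMap) -> AnnotationResult:
    """Locate a variant in the domain map (total over positive positions)."""
    domain = m.domain_of(v.position)
    notes = "" if v.alt_aa is not None else "substitution unspecified (position-only input)"
    return AnnotationResult(
        variant=v,
        domain=domain,
        sub_element=m.sub_element_of(v.position),
        notes=notes,
        raw=v.raw,
    )


def annotate_table(variants: Sequence[str], m: DomainMap) -> List[AnnotationResult]:
    """Annotate a list of variant strings, preserving input order.

    Parse failures become error rows rather than aborting the table.
    """
    if not variants:
        raise ValueError("annotate_table requires a nonempty variant list")
    rows: List[AnnotationResult] = []
    for s in variants:
        try:
            v = parse_variant_token(s)
        except HgvsParseError as exc:
            rows.append(AnnotationResult(None, "", raw=s, error=str(exc)))
            continue
        rows.append(assign_domain(v, m))
    return rows


def annotation_rows(results: Sequence[AnnotationResult]) -> List[Tuple[str, str, str, str]]:
    """Flatten results to (input, domain, sub-element, notes/error) tuples."""
    out = []
    for r in results:
        if not r.ok:
            out.append((r.raw, "ERROR", "", r.error or ""))
        else:
            out.append((r.raw, r.domain, r.sub_element or "", r.notes))
    return out
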