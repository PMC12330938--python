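"""Conformational-state classification of kinase-domain structures.

The αC-helix "in"/"out" state of the MET kinase domain is read off two
mutually exclusive salt bridges:

* **inactive** (αC out): αJM-helix H1086 – αC-helix D1151 bridged, while
  the catalytic-lysine bridge K1128 – E1145 is broken;
* **active** (αC in): K1128 – E1145 bridged, H1086 – D1151 broken.

Both filters are applied as classifiers rather than pre-filters: a
structure where both bridges are formed is a ``conflict``, where both are
broken an ``indeterminate``, so the mutual-exclusivity claim of the
two-state model is itself testable on any structure set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .config import Config
from .geometry import BridgeMeasurement, measure_bridge
from .io import read_structure, select_frame
from .model import Frame, StructureError, StructureModel
from .numbering import resolve_numbering, wildtype_filter

#: Call states, in report order.
STATES = (
    "inactive",
    "active",
    "conflict",
    "indeterminate",
    "unmeasurable",
    "excluded_non_wildtype",
    "excluded_unresolved",
)


@dataclass
class ConformationCall:
    entry_id: str
    state: str
    bridge_evidence: Dict[str, BridgeMeasurement] = field(default_factory=dict)
    chain_id: str = ""
    offset: Optional[int] = None
    wildtype: Optional[bool] = None
    reasons: List[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "entry_id": self.entry_id,
            "state": self.state,
            "chain_id": self.chain_id,
            "offset": self.offset,
            "wildtype": self.wildtype,
            "reasons": self.reasons,
            "bridges": {k: v.to_dict() for k, v in self.bridge_evidence.items()},
        }


def state_from_bridges(inactive_marker: BridgeMeasurement,
                       active_marker: BridgeMeasurement) -> str:
    """Total state table over {present, absent, unmeasurable}²."""
    if not inactive_marker.measurable or not active_marker.measurable:
        return "unmeasurable"
    if inactive_marker.present and active_marker.present:
        return "conflict"
    if inactive_marker.present:
        return "inactive"
    if active_marker.present:
        return "active"
    return "indeterminate"


def classify_frame(frame: Frame, config: Config) -> ConformationCall:
    """Classify one already-selected chain."""
    resolution = resolve_numbering(
        frame.residues, config.residue_specs, config.candidate_offsets
    )
    if not resolution.resolved:
        return ConformationCall(
            entry_id=frame.entry_id,
            state="excluded_unresolved",
            chain_id=frame.chain_id,
            reasons=[f"numbering {resolution.status}"],
        )

    wt = wildtype_filter(
        frame.residues, resolution, config.residue_specs,
        bridge_positions=config.bridge_position_atoms(),
    )
    if not wt.passed and wt.reason == "non-wildtype":
        return ConformationCall(
            entry_id=frame.entry_id,
            state="excluded_non_wildtype",
            chain_id=frame.chain_id,
            offset=resolution.offset,
            wildtype=False,
            reasons=[f"non-wildtype at {wt.failing_positions}"],
        )

    evidence = {
        b.name: measure_bridge(frame.residues, resolution, b) for b in config.bridges
    }
    names = [b.name for b in config.bridges]
    state = state_from_bridges(evidence[names[0]], evidence[names[1]])
    reasons: List[str] = []
    if not wt.passed:  # unmeasurable bridge residues
        state = "unmeasurable"
        reasons.append(f"bridge residues unobserved/incomplete at {wt.failing_positions}")
    return ConformationCall(
        entry_id=frame.entry_id,
        state=state,
        bridge_evidence=evidence,
        chain_id=frame.chain_id,
        offset=resolution.offset,
        wildtype=wt.passed,
        reasons=reasons,
    )


def classify_model(s: StructureModel, config: Config) -> ConformationCall:
    """Classify a parsed structure (chain auto-selected)."""
    try:
        frame = select_frame(
            s,
            model_index=min(config.model_index, s.n_models()),
            required_position_sets=config.required_position_sets(),
        )
    except StructureError as exc:
        return ConformationCall(
            entry_id=s.entry_id, state="unmeasurable", reasons=[str(exc)]
        )
    return classify_frame(frame, config)


def classify_structure(path: str, config: Config) -> ConformationCall:
    """Full pipeline for one file: read → select → resolve → filter → measure.

    Parse failures raise; every biological or geometric failure is encoded
    in the returned state.
    """
    return classify_model(read_structure(path), config)


@dataclass
class SurveyReport:
    calls: List[ConformationCall]
    errors: Dict[str, str] = field(default_factory=dict)
    config_hash: str = ""

    @property
    def groups(self) -> Dict[str, List[str]]:
        out: Dict[str, List[str]] = {s: [] for s in STATES}
        for c in self.calls:
            out.setdefault(c.state, []).append(c.entry_id)
        return {k: sorted(v) for k, v in out.items() if v}

    @property
    def mutually_exclusive(self) -> bool:
        return not any(c.state == "conflict" for c in self.calls)

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "mutually_exclusive": self.mutually_exclusive,
            "groups": self.groups,
            "calls": [c.to_dict() for c in self.calls],
            "errors": self.errors,
        }


def run_survey(paths: Sequence[str], config: Config) -> SurveyReport:
    """Classify a set of structure files into conformational groups.

    Individual file failures are recorded per entry and never abort the
    survey.  Output order is deterministic (sorted by entry id).
    """
    if not paths:
        raise ValueError("run_survey requires at least one structure path")
    calls: List[ConformationCall] = []
    errors: Dict[str, str] = {}
    for path in paths:
        try:
            calls.append(classify_structure(str(path), config))
        except StructureError as exc:
            import os
            errors[os.path.splitext(os.path.basename(str(path)))[0]] = str(exc)
    calls.sort(key=lambda c: c.entry_id)
    return SurveyReport(calls=calls, errors=errors, config_hash=config.content_hash)


def mutual_exclusivity_check(report: SurveyReport) -> Tuple[bool, List[str]]:
    """True iff no classified entry forms both marker bridges."""
    offenders = sorted(
        c.entry_id for c in report.calls
        if all(m.measurable and m.present for m in c.bridge_evidence.values())
        and len(c.bridge_evidence) >= 2
    )
    return (not offenders, offenders)


# ---------------------------------------------------------------------------
# serialization

TSV_COLUMNS = (
    "entry_id", "state", "HD_min_A", "HD_pair", "KE_min_A", "KE_pair",
    "offset", "wildtype", "reasons",
)


def _fmt_measure(m: Optional[BridgeMeasurement]) -> Tuple[str, str]:
    if m is None or m.min_distance is None:
        return ("NA", "NA")
    return (f"{m.min_distance:.2f}", "-".join(m.min_pair))


def report_tsv(report: SurveyReport) -> str:
    lines = ["\t".join(TSV_COLUMNS)]
    for c in report.calls:
        hd_d, hd_p = _fmt_measure(c.bridge_evidence.get("HD"))
        ke_d, ke_p = _fmt_measure(c.bridge_evidence.get("KE"))
        lines.append("\t".join([
            c.entry_id, c.state, hd_d, hd_p, ke_d, ke_p,
            "NA" if c.offset is None else str(c.offset),
            "NA" if c.wildtype is None else str(c.wildtype).lower(),
            ";".join(c.reasons) or "-",
        ]))
    return "\n".join(lines) + "\n"


def report_json(report: SurveyReport) -> str:
    return json.dumps(report.to_dict(), indent=2, sort_keys=True)
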