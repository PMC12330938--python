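"""Configuration loading, validation and provenance hashing.

A single YAML file carries every constant the survey depends on: marker
residues, salt-bridge definitions and cutoffs, hydrophobic-contact pairs,
candidate numbering offsets, and the domain map used for variant
annotation.  Validation is strict — unknown keys are rejected and every
constraint violation names the offending key — and a content hash of the
canonicalized document is embedded in reports for provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import yaml

from .geometry import BridgeEnd, ContactSpec, SaltBridgeSpec
from .numbering import ResidueSpec
from .variants import DomainInterval, DomainMap


class ConfigError(ValueError):
    """Configuration file violates the schema."""


_TOP_KEYS = {
    "candidate_offsets", "model_index", "residue_specs", "bridges",
    "contacts", "domains", "kinase_sub_elements",
}


def _require_keys(mapping: dict, allowed: set, required: set, where: str) -> None:
    if not isinstance(mapping, dict):
        raise ConfigError(f"{where}: expected a mapping, got {type(mapping).__name__}")
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"{where}: unknown key(s) {sorted(unknown)}")
    missing = required - set(mapping)
    if missing:
        raise ConfigError(f"{where}: missing key(s) {sorted(missing)}")


def _residue_spec(raw: dict, where: str) -> ResidueSpec:
    _require_keys(raw, {"position", "aa", "label", "atoms"}, {"position", "aa"}, where)
    try:
        return ResidueSpec(int(raw["position"]), str(raw["aa"]), str(raw.get("label", "")))
    except ValueError as exc:
        raise ConfigError(f"{where}: {exc}") from exc


@dataclass
class Config:
    residue_specs: List[ResidueSpec]
    bridges: List[SaltBridgeSpec]
    contacts: List[ContactSpec]
    candidate_offsets: Tuple[int, ...]
    domain_map: DomainMap
    model_index: int = 1
    content_hash: str = ""

    def bridge_position_atoms(self) -> Dict[int, Tuple[str, ...]]:
        """Isoform position -> atom names a bridge measurement needs."""
        out: Dict[int, Tuple[str, ...]] = {}
        for b in self.bridges:
            out[b.donor.spec.paper_position] = b.donor.atoms
            out[b.acceptor.spec.paper_position] = b.acceptor.atoms
        return out

    def bridge_positions(self) -> List[int]:
        return sorted(self.bridge_position_atoms())

    def required_position_sets(self) -> List[set]:
        """One author-number set per candidate offset (bridge residues only)."""
        positions = self.bridge_positions()
        return [
            {p + off for p in positions} for off in self.candidate_offsets
        ]


def _parse_config(doc: dict, content_hash: str) -> Config:
    _require_keys(doc, _TOP_KEYS, {"residue_specs", "bridges", "domains"}, "config")

    specs = [
        _residue_spec(r, f"residue_specs[{i}]")
        for i, r in enumerate(doc["residue_specs"])
    ]
    spec_by_pos = {s.paper_position: s for s in specs}

    bridges: List[SaltBridgeSpec] = []
    for i, raw in enumerate(doc["bridges"]):
        where = f"bridges[{i}]"
        _require_keys(
            raw, {"name", "label", "donor", "acceptor", "cutoff"},
            {"name", "donor", "acceptor"}, where,
        )
        cutoff = float(raw.get("cutoff", 4.0))
        if cutoff <= 0:
            raise ConfigError(f"{where}.cutoff: must be positive, got {cutoff}")
        ends = {}
        for side in ("donor", "acceptor"):
            end_raw = dict(raw[side])
            atoms = end_raw.pop("atoms", None)
            if not atoms:
                raise ConfigError(f"{where}.{side}.atoms: nonempty atom list required")
            spec = _residue_spec(end_raw, f"{where}.{side}")
            ends[side] = BridgeEnd(spec, tuple(str(a) for a in atoms))
        bridges.append(SaltBridgeSpec(str(raw["name"]), ends["donor"], ends["acceptor"], cutoff))

    contacts: List[ContactSpec] = []
    for i, raw in enumerate(doc.get("contacts", [])):
        where = f"contacts[{i}]"
        _require_keys(raw, {"a", "b", "cutoff"}, {"a", "b"}, where)
        cutoff = float(raw.get("cutoff", 4.5))
        if cutoff <= 0:
            raise ConfigError(f"{where}.cutoff: must be positive, got {cutoff}")
        contacts.append(
            ContactSpec(
                _residue_spec(raw["a"], f"{where}.a"),
                _residue_spec(raw["b"], f"{where}.b"),
                cutoff,
            )
        )

    def _intervals(key: str) -> List[DomainInterval]:
        out = []
        for i, raw in enumerate(doc.get(key, [])):
            where = f"{key}[{i}]"
            _require_keys(raw, {"name", "start", "end"}, {"name", "start", "end"}, where)
            try:
                out.append(DomainInterval(str(raw["name"]), int(raw["start"]), int(raw["end"])))
            except ValueError as exc:
                raise ConfigError(f"{where}: {exc}") from exc
        return out

    try:
        domain_map = DomainMap(_intervals("domains"), _intervals("kinase_sub_elements"))
    except ValueError as exc:
        raise ConfigError(f"domain map: {exc}") from exc

    offsets = tuple(int(o) for o in doc.get("candidate_offsets", (0, -18)))
    if not offsets:
        raise ConfigError("candidate_offsets: must be nonempty")
    model_index = int(doc.get("model_index", 1))
    if model_index < 1:
        raise ConfigError(f"model_index: must be >= 1, got {model_index}")

    # every bridge end must also be a configured marker so the wild-type
    # filter covers the bridge-defining quartet
    for b in bridges:
        for end in (b.donor, b.acceptor):
            pos = end.spec.paper_position
            if pos not in spec_by_pos:
                raise ConfigError(
                    f"bridge {b.name}: position {pos} missing from residue_specs"
                )
            if spec_by_pos[pos].expected_aa != end.spec.expected_aa:
                raise ConfigError(
                    f"bridge {b.name}: identity conflict at position {pos}"
                )

    return Config(
        residue_specs=specs,
        bridges=bridges,
        contacts=contacts,
        candidate_offsets=offsets,
        domain_map=domain_map,
        model_index=model_index,
        content_hash=content_hash,
    )


def _hash_doc(doc: dict) -> str:
    canonical = json.dumps(doc, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def load_config(path: str) -> Config:
    """Load and validate a YAML configuration file."""
    try:
        with open(path) as fh:
            doc = yaml.safe_load(fh)
    except OSError as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    except yaml.YAMLError as exc:
        raise ConfigError(f"invalid YAML in {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return _parse_config(doc, _hash_doc(doc))


def default_config() -> Config:
    """The packaged MET defaults."""
    text = resources.files("metconf.data").joinpath("met_default.yaml").read_text()
    doc = yaml.safe_load(text)
    return _parse_config(doc, _hash_doc(doc))


def default_config_path() -> str:
    return str(resources.files("metconf.data").joinpath("met_default.yaml"))
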