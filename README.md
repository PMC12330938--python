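# metconf

Conformational-state survey of MET receptor tyrosine-kinase domain crystal
structures, driven by two mutually exclusive salt bridges, plus HGVS
variant-to-domain annotation for the MET receptor.

## The problem

Activating MET mutations found in hereditary papillary renal cell carcinoma
(HPRCC) and non-small-cell lung cancer cluster in the N-lobe of the kinase
domain, around the interface between the juxtamembrane helix (αJM-helix)
and the αC-helix. Whether a given kinase-domain crystal structure shows an
αC-helix "in" (catalytically competent, *active*) or "out" (*inactive*)
arrangement can be read from local side-chain geometry:

* **inactive marker** — a salt bridge between the αJM-helix histidine
  H1086 and the αC-helix aspartate D1151;
* **active marker** — the canonical protein-kinase salt bridge between the
  β3 catalytic lysine K1128 and the αC-helix glutamate E1145.

A salt bridge is operationalized the standard way: minimum distance over
the grid of basic side-chain nitrogens × acidic carboxylate oxygens
(His {ND1, NE2}, Lys {NZ} × Asp {OD1, OD2}, Glu {OE1, OE2}), present when
≤ 4.0 Å. In wild-type MET kinase-domain structures the two bridges are
mutually exclusive, so each structure receives one of two states — or an
explicit non-state (`conflict`, `indeterminate`, `unmeasurable`,
`excluded_non_wildtype`, `excluded_unresolved`) that says why not.

Positions above are long-isoform numbering (MET transcript variant 1,
NM_001127500.1). Most PDB depositions number the short isoform, 18
residues behind (K1128 ↔ K1110); the package resolves the offset per
structure by checking marker-residue identities under candidate offsets
{0, −18} and refuses to guess when the evidence is ambiguous.

## Worked example

```python
import metconf as mc

cfg = mc.default_config()
structure = mc.build_fixture(
    mc.FixtureRecipe(name="demo", targets={"HD": 3.5, "KE": 9.0}), cfg)
call = mc.classify_model(structure, cfg)
print(call.state)
for name, m in call.bridge_evidence.items():
    print(name, round(m.min_distance, 2), m.min_pair, m.present)
```

prints

```
inactive
HD 3.5 ('NE2', 'OD2') True
KE 9.0 ('NZ', 'OE2') False
```

i.e. the H1086–D1151 bridge is formed at 3.50 Å through the His NE2 /
Asp OD2 pair while the K1128–E1145 bridge is broken (9.00 Å), the
fingerprint of the inactive, αC-helix-out conformation. The `examples/`
directory has one short script per capability: single-structure
classification, the full survey with its truth-table check, variant
annotation, low-level bridge/contact/polar-scan geometry, and the
real-entry survey.

The same operations are exposed as a thin CLI:

```bash
metconf simulate --out suite/           # synthetic fixture suite + truth table
metconf survey --structures suite/ --out report   # report.tsv + report.json
metconf classify suite/syn_iso_inactive.pdb
metconf annotate --variants variants.txt
```

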