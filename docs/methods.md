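# Methods

## Model

The package classifies the αC-helix disposition of MET kinase-domain
structures from two side-chain salt bridges. A salt bridge between
residues *i* (basic) and *j* (acidic) is declared from the minimum
Euclidean distance over the donor × acceptor heavy-atom grid:

    d(i, j) = min over N in donor(i), O in acceptor(j) of ||x_N − x_O||

with donor sets His {ND1, NE2}, Lys {NZ} and acceptor sets Asp {OD1, OD2},
Glu {OE1, OE2}. The bridge is *present* when d ≤ c. The two configured
bridges are the inactive marker H1086–D1151 (αJM-helix to αC-helix) and
the active marker K1128–E1145 (β3 catalytic lysine to αC-helix glutamate),
long-isoform numbering throughout.

The per-structure state is a total function of the two presence flags:
present/absent → `inactive`; absent/present → `active`; both present →
`conflict`; both absent → `indeterminate`; either bridge unmeasurable →
`unmeasurable`. Mutations at marker positions give
`excluded_non_wildtype`, unresolvable numbering `excluded_unresolved`.
Applying the two bridge criteria as a classifier rather than a pre-filter
keeps every structure in the report, which is what makes the
mutual-exclusivity claim — no classified structure forms both bridges —
falsifiable on any input set rather than true by construction.

### Assumptions

* Distance-only criterion: no donor–acceptor angles, protonation states or
  electrostatics. Taking the minimum over chemically equivalent atoms is
  the standard operationalization when a single literature distance does
  not name its atoms; the full pair grid is reported so any printed value
  can be located among the 2×2 combinations.
* Single-conformer view: one model (the first), one chain, one altloc per
  atom. Crystallographic averaging beyond that is out of scope.
* Heavy atoms only; hydrogens, if deposited, are ignored.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| salt-bridge cutoff c | 4.0 | Å | Barlow–Thornton-style convention; any value between the bridged (~3.4–3.9 Å) and broken (~7.4 Å) regimes yields the same partition of the reference structures |
| hydrophobic-contact cutoff | 4.5 | Å | common van-der-Waals contact convention for side-chain heavy atoms |
| candidate numbering offsets | {0, −18} | residues | long-isoform vs short-isoform MET numbering; configurable for other kinases |
| model index | 1 | – | cited crystal structures are single-model |
| distance reporting | 0.01 | Å | PDB fixed-width coordinates carry 3 decimals; assertions against one-decimal literature values use ±0.05 Å |

All constants live in one YAML document (`metconf/data/met_default.yaml`);
a SHA-256 content hash of the canonicalized document is embedded in every
report for provenance. Unknown keys are rejected.

## Numbering resolution

Author numbering is mapped to isoform numbering by offset trial, not
sequence alignment: for each candidate offset, every configured marker
residue whose mapped position exists in the chain is identity-checked.
One offset matching all present markers wins; several matching is
`ambiguous` (never silently resolved). When no offset is perfect, a
unique offset matching ≥ 75% of its present markers (and at least three)
is accepted so that a structure carrying a point mutation at a marker
position can still be numbered — and then reported as non-wild-type by
the wild-type filter, rather than becoming unresolvable. Seventeen marker
residues (the bridge quartet, the αJM/αC hydrophobic interface, the β-
sheet histidines, hinge, DFG aspartate, C-lobe methionine) back the check,
so a coincidental match of a wrong offset would need many simultaneous
identity collisions.

A disordered (unobserved or side-chain-less) bridge residue makes the
structure `unmeasurable`, never "bridge absent": absence of evidence is
not a broken bridge.

## Frame selection

Default chain: the first chain in file order containing all four
bridge-defining author positions under some candidate offset; the chosen
chain is recorded in the call. Altlocs: per atom name, highest occupancy
wins, ties broken by file order. Insertion-coded residues are carried but
marker matching requires an empty insertion code (the MET entries have
none at marker sites). Waters are stripped at parse time; non-polymer
heteroatom groups (ATP, inhibitors) are kept as flagged groups so ligands
are never silently dropped.

## Synthetic structures

The generator emulates exactly what the classifier consumes: single-chain
arrangements of the seventeen marker residues (His/Asp/Lys/Glu and the
hydrophobic interface residues) with idealized internal geometry, placed
≥ 12 Å apart except for bridge partners. For a requested bridge distance
*d*, the acceptor residue is rotated so its Cα points away along the unit
vector **u** from the donor Cα through the donor's outermost bridging
atom, and its outermost acceptor atom is placed at that atom + *d*·**u**.
Every other donor atom then lies behind the designed donor atom and every
other acceptor atom beyond the designed acceptor atom, so the designed
pair is the grid minimum; the builder re-measures each bridge and refuses
to emit a fixture deviating by more than 0.02 Å (the slack covers the
0.001 Å PDB column rounding). Seeded randomness is used only to jitter
non-bridge residues; bridge geometry is analytic, and a fixed seed yields
bit-identical files.

What the fixtures deliberately do not model: backbone continuity,
rotamer realism, crystal packing, solvent, B-factors. Passing the
closed-loop suite therefore demonstrates correctness of parsing,
selection, numbering, filtering and distance logic under controlled
geometry — it does not validate the 4.0 Å cutoff against experimental
conformational labels, which only real structures can do.

The canonical suite covers both numbering offsets, all five geometric
call states plus both exclusion states, altloc ties and
occupancy-majority cases, a dropped acceptor side chain, marker-residue
mutants (β1 Ile→Thr, catalytic Lys→Met), a two-chain file whose first
chain is incomplete, a two-model file, and the 3.95/4.05 Å
cutoff-bracketing pair; each fixture is written both as PDB and as an
mmCIF mirror, with state truths designed at least 0.05 Å away from the
cutoff so format precision cannot flip them.

## Variant annotation

HGVS protein substitutions (`p.(Ile1102Thr)`, with or without
parentheses) are parsed strictly; the table-level API additionally
accepts one-letter shorthand and a position-only token (`I1102`, as
printed in one reported row whose substitution is not stated), which is
annotated by position and flagged "substitution unspecified" rather than
guessed or dropped. The domain map is shipped as configuration because
the clinical literature provides anchors, not boundaries: intervals were
drawn from standard MET domain annotations shifted to long-isoform
numbering, then validated against the ten-variant panel assignments and
the kinase sub-element anchors (αJM-helix ending at 1086, β1 holding
1102, β2–β3 holding 1112/1124/1125/1128/1130, αC-helix holding 1145/1151,
hinge holding 1176/1178, DFG aspartate 1240 opening the activation loop,
C-lobe holding 1268). Inter-element gaps legitimately annotate to the
kinase domain with no sub-element.

## Numerical choices and degenerate inputs

* Distances are exact numpy norms; no cutoff-dependent optimizations.
* Comparisons against one-decimal literature distances use ±0.05 Å.
* Zero-polymer files, unparseable files and absent chains raise typed
  errors; within a survey they are recorded per entry and never abort the
  batch.
* An empty survey report is vacuously mutually exclusive.
* `polar_neighbor_scan` returns `None` (not an empty list) when the
  center side chain is unobserved, distinguishing "nothing nearby" from
  "cannot measure".

## Problem sizes

The default test suite and the acceptance script run entirely on
generated inputs: 19 fixtures × 2 formats for the closed loop, 100–120
random residue pairs for the brute-force and rigid-body oracles, and a
labelled seven-structure demo partition. These sizes were chosen because
every additional fixture exercises the same finite state table; coverage,
not volume, is the design axis. The real-structure survey (seven public
PDB entries) runs whenever local copies are supplied and takes seconds.

## Known limitations

* The offset resolver assumes a single-domain, single-protein scope; it
  is not a SIFTS-style alignment and would need new marker tables for
  other kinases.
* No DFG-in/out or activation-loop classification: the two-bridge
  criterion reads only the αJM/αC interface and the catalytic-lysine
  bridge.
* The 4.0 Å cutoff is a convention, not a fitted parameter; structures
  with genuinely intermediate αC-helix positions will fall into
  `indeterminate` rather than being interpolated.
* Sub-element boundaries between anchor residues are approximate by a few
  residues; only the anchors themselves are validated.
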