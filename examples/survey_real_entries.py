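"""Survey the seven cited MET kinase-domain crystal structures.

Requires local copies of the public PDB entries under
``data/met_structures/`` (they are not redistributed with the package):

    metconf fetch 1R1W 2G15 3F66 4KNB 3Q6W 3R7O 4IWD

The expected outcome is a 4/3 split: an inactive group {1R1W, 2G15, 3F66,
4KNB} whose H1086-D1151 bridge is formed, and an active group {3Q6W, 3R7O,
4IWD} whose K1128-E1145 bridge is formed, with no structure in both.
"""

from pathlib import Path

import metconf as mc

ENTRIES = ("1R1W", "2G15", "3F66", "4KNB", "3Q6W", "3R7O", "4IWD")
structure_dir = Path(__file__).resolve().parents[1] / "data" / "met_structures"

paths = [structure_dir / f"{e}.pdb" for e in ENTRIES]
missing = [p.name for p in paths if not p.exists()]
if missing:
    raise SystemExit(
        f"missing {missing} under {structure_dir}; run `metconf fetch {' '.join(ENTRIES)}`"
    )

cfg = mc.default_config()
report = mc.run_survey([str(p) for p in paths], cfg)
print(mc.report_tsv(report))
print("groups:", {k: v for k, v in report.groups.items()})
ok, offenders = mc.mutual_exclusivity_check(report)
print(f"mutually exclusive: {ok} (offenders: {offenders})")
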