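"""Classify a single kinase-like structure from its salt-bridge fingerprint.

Builds a synthetic structure whose αJM-helix His/αC-helix Asp bridge is
formed at 3.5 Å while the catalytic Lys/αC-helix Glu bridge is broken
(9 Å), then runs the classifier on it.
"""

import metconf as mc

cfg = mc.default_config()
recipe = mc.FixtureRecipe(name="demo", targets={"HD": 3.5, "KE": 9.0})
structure = mc.build_fixture(recipe, cfg)
call = mc.classify_model(structure, cfg)

print(f"state: {call.state}")
for name, m in call.bridge_evidence.items():
    print(f"  bridge {name}: min {m.min_distance:.2f} Å over pair {m.min_pair}, "
          f"present={m.present} (cutoff {m.cutoff} Å)")

# A formed H1086-D1151 bridge with a broken K1128-E1145 bridge is the
# signature of the inactive, aC-helix "out" conformation.
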