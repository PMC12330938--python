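"""Map the reported MET variant panel onto receptor domains.

Parses the ten HGVS protein substitutions from the HPRCC/NSCLC screening
panel and assigns each to a MET domain and, within the kinase domain, to a
structural sub-element.
"""

import metconf as mc
from metconf.variants import MET_VARIANT_PANEL

cfg = mc.default_config()
rows = mc.annotate_table(MET_VARIANT_PANEL, cfg.domain_map)

print(f"{'variant':<18s} {'domain':<24s} sub-element")
for r in rows:
    print(f"{r.raw:<18s} {r.domain:<24s} {r.sub_element or '-'}"
          + (f"   [{r.notes}]" if r.notes else ""))

counts = {}
for r in rows:
    counts[r.domain] = counts.get(r.domain, 0) + 1
print("\ndomain counts:", counts)
# Expected: 2 SEMA, 2 juxtamembrane, 6 kinase-domain variants; the N-lobe
# cluster (1086-1130) is what motivates the conformational survey.
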