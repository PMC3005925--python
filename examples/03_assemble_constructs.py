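"""Assemble the study's constructs step by step and inspect the scars.

Starts from the synthetic platform plasmid, installs the constitutive
Placq promoter part upstream, then inserts the LacI operator part twice
into the downstream standard region. After every insertion the platform
still has exactly one BglII and one MluI entry site — the idempotence the
standard exists for: the BamHI/BglII fusion scar is cut by neither enzyme
while the part brings a fresh BglII site, and the MluI joint re-creates
ACGCGT.
"""

from opergate import (
    build_synthetic_backbone,
    insert_downstream,
    insert_upstream,
    lac_operator_part,
    placq_part,
    validate_platform,
)

plasmid = build_synthetic_backbone()
print(f"pSB-GFP stand-in: {len(plasmid.top)} bp, "
      f"conforms={validate_platform(plasmid).conforms}")

plasmid = insert_upstream(plasmid, placq_part(), ("SalI", "BglII"))
plasmid.name = "Placq-GFP"
down = plasmid.features_by_role("downstream_region")[0]
print(f"Placq-GFP: {len(plasmid.top)} bp, conforms={validate_platform(plasmid).conforms}, "
      f"downstream region 5'-{plasmid.top[down.start:down.end]}-3'")

for label in ("Placq-LacI-GFP", "Placq-LacItandem-GFP"):
    plasmid = insert_downstream(plasmid, lac_operator_part())
    plasmid.name = label
    left, right = plasmid.junctions
    print(f"{label}: {len(plasmid.top)} bp, conforms={validate_platform(plasmid).conforms}")
    print(f"  BamHI/BglII scar 5'-{left.sealed_sequence}-3' recuttable by "
          f"{sorted(left.recuttable_by) or 'nothing'}")
    print(f"  MluI joint      5'-{right.sealed_sequence}-3' recuttable by "
          f"{sorted(right.recuttable_by)}")

operators = plasmid.features_by_role("operator")
print(f"operators 5'->3': {[f.label for f in operators]} "
      f"at {[(f.start, f.end) for f in operators]}")
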