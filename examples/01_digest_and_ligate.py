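"""Digest a plasmid and seal the fragments back together.

Builds the synthetic platform plasmid, cuts it with BglII and MluI, shows
the sticky-end structure of the released stuffer, then re-ligates and
circularizes the fragments. The numbers to watch: fragment lengths sum to
the plasmid length (digestion conserves material) and the re-ligated
circle has the same sequence as the input up to the choice of origin.
"""

from opergate import build_synthetic_backbone, digest, ligate, lookup

plasmid = build_synthetic_backbone()
print(f"platform plasmid: {len(plasmid.top)} bp, circular")

frags = digest(plasmid, {lookup("BglII"), lookup("MluI")})
for frag in frags:
    print(
        f"  fragment {len(frag.top):>5} bp   "
        f"left 5'-{frag.left_end.overhang} ({frag.left_end.strand} strand)   "
        f"right 5'-{frag.right_end.overhang} ({frag.right_end.strand} strand)"
    )
stuffer = min(frags, key=lambda f: len(f.top))
print(f"released stuffer top strand: 5'-{stuffer.top}-3'")
print(f"lengths conserved: {sum(len(f.top) for f in frags) == len(plasmid.top)}")

rejoined = ligate(frags, circularize=True)
print(f"re-ligated: {len(rejoined.top)} bp, rotation of the input: "
      f"{rejoined.top in plasmid.top + plasmid.top}")
for j in rejoined.junctions:
    print(f"  junction sealed 5'-{j.sealed_sequence}-3', recuttable by "
          f"{sorted(j.recuttable_by) or 'nothing'}")
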