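# opergate

In-silico restriction cloning and genetic-logic analysis for a modular
promoter-engineering standard: simulate digestion and sticky-end ligation,
insert standardized operator parts into a plasmid's regulatory region over
and over, and derive the Boolean gate (NULL, BUFFER, AND, ...) the
assembled promoter implements.

## The problem and the standard

Classic composable-DNA-part standards let you append parts to either end of
an existing assembly, but not *between* two parts that are already joined —
exactly what promoter engineering needs, because tuning a promoter means
dropping operator sites (repressor/activator binding sites) into an
existing regulatory region.

The standard modeled here splits a reporter plasmid's regulatory region in
two:

* an **upstream multi-cloning region** (EcoRI, XbaI, SalI, BamHI) that
  receives the −35/−10 promoter part, and
* a **downstream standard region** (BglII, MluI), just upstream of the RBS,
  that receives operator parts repeatedly.

A downstream operator part is an annealed oligo duplex shaped as

```
5'-GATC <operator> AGATCT <spacer>-3'
        3'-<operator'> TCTAGA <spacer'> GCGC-5'
```

i.e. a BamHI-made `GATC` sticky end, the operator, a fresh BglII site, a
spacer, and an MluI-made `CGCG` sticky end. BamHI (`G^GATCC`) and BglII
(`A^GATCT`) are isocaudamers — different recognition sites, identical
`GATC` overhangs — so the part ligates into a BglII+MluI-cut plasmid, the
fusion scar is cut by *neither* enzyme, and the part's internal `AGATCT`
becomes the region's new BglII site. Insertion is therefore idempotent: the
product accepts the next part by the same two-enzyme digest, indefinitely.

Transcription logic is Boolean: a strong constitutive −35/−10 fires
unconditionally; a weak activator-dependent core (luxpR) fires only when
its activator (LuxR) is available and induced (AHL); any repressor-bound
operator (LacI, released by IPTG) silences the unit. One LuxR operator
upstream plus two lac operators downstream of a weak core yields
`output = AHL AND IPTG` — a genetic AND gate.

## Worked example

```python
from opergate import (build_synthetic_backbone, insert_upstream,
                      insert_downstream, placq_part, lac_operator_part,
                      extract_model, truth_table)

plasmid = build_synthetic_backbone()                      # 2313 bp platform
plasmid = insert_upstream(plasmid, placq_part(), ("SalI", "BglII"))
plasmid = insert_downstream(plasmid, lac_operator_part())
left, right = plasmid.junctions
print(left.sealed_sequence, sorted(left.recuttable_by))   # GAGATCGG []
print(right.sealed_sequence, sorted(right.recuttable_by)) # AACGCGTG ['MluI']
print(truth_table(extract_model(plasmid, {"LacI"})).as_dict())
```

prints

```
GAGATCGG []
AACGCGTG ['MluI']
{'inputs': ['IPTG'], 'rows': {'none': 'OFF', 'IPTG': 'ON'}, 'gate': 'BUFFER'}
```

The first line is the BamHI/BglII fusion scar — recuttable by nothing, so
the inserted operator is locked in place; the second shows the regenerated
MluI entry site. The truth table says the construct expresses only when
IPTG releases the LacI repressor. Inserting a second lac operator part and
swapping the constitutive promoter for the LuxR cassette turns the table
into the AND gate (`examples/04_truth_tables.py` prints all six constructs
in two host strains).

The `examples/` directory holds one short narrative script per capability:
digestion/ligation, part design, iterative assembly with scar analysis, and
truth-table derivation. A thin CLI wraps the same library:

```bash
opergate fixture make-and-gate --strain DH5alphaLacI
opergate digest --enzymes BglII,MluI --in plasmid.gb --out frags.fa
opergate simulate --plasmid product.gb --strain DH5alphaLacI --format json
```

## Scope

Boolean semantics only: no Hill functions, expression levels or
fold-change prediction. Complete digestion (no partial digests, star
activity or methylation sensitivity), designed single-insert ligation
products only (no concatemers or re-closure), and 5'-overhang type-II
chemistry only. The platform backbone and the LuxR cassette are synthetic
stand-ins built around the published primer/oligo sequences; see
`docs/methods.md`.
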