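# Methods

## Sequence model

DNA is represented exactly: uppercase A/C/G/T only, with IUPAC ambiguity
codes rejected rather than expanded. Every sequence the toolkit reasons
about (printed oligos, primers, assembled products) is fully specified, and
exact semantics keep digestion and ligation deterministic. Coordinates are
0-based, half-open, on the top strand; circular molecules carry a fixed
origin chosen at construction and no ends.

A linear `DuplexFragment` stores its complete top strand plus two end
descriptors. An end is blunt or a 5' overhang written 5'→3' on the
protruding strand; with 5'-overhang chemistry a left end can only protrude
on the top strand and a right end only on the bottom strand, and the
constructor enforces this, so which strand protrudes is always unambiguous.
3' overhangs are representable (a reserved end kind) but every operation
refuses them — no enzyme in scope produces them, and silently mis-ligating
one would be worse than an error. The bottom strand is derived on demand
as (right overhang) + reverse-complement(core) and is never stored, so the
two strands cannot drift apart.

### Annealing

`anneal_oligos` enumerates every ungapped antiparallel alignment of the two
oligos in which all paired positions are complementary and unpaired bases
occur only as terminal 5' extensions. Alignments pairing fewer than 4 bases
(`MIN_DUPLEX`, the length of the sticky ends in scope) are not counted as
annealed states: nearly every oligo pair shows chance 1–2 bp terminal
complementarity, and treating those as real alignments would make almost
any input "ambiguous" — including the two synthesized oligo pairs this
package ships. Among the remaining alignments exactly one must survive;
several (e.g. `GATCGATC`/`GATCGATC`, which supports both a blunt 8-bp state
and a 4-nt-overhang state) raise an ambiguity error rather than guess,
because a silent choice could build the wrong part.

## Restriction engine

The seven enzymes (EcoRI, XbaI, SalI, BamHI, BglII, MluI, SpeI) are
palindromic 6-cutters leaving 4-nt 5' overhangs. Their cut geometries are
encoded from the standard REBASE definitions in a versioned YAML data file
(`src/opergate/data/enzymes.yaml`); the table is data, not code, and any
operation can be run against a user-supplied table of the same shape.

Site finding requires the full recognition site to be double-stranded: a
site whose span reaches into a single-stranded overhang of a linear
fragment is not reported. Digestion is complete — every accessible site is
cut — with one deliberate refinement: when two sites overlap so closely
that one cut would land inside the single-stranded overhang left by the
other (possible in random sequence, never in the designed constructs), the
leftmost-from-origin cut wins and the blocked site survives uncut. Without
this rule "cut everything" would demand fragments with negative-length
duplex cores. Partial digestion, star activity, methylation sensitivity
and kinetics are all out of scope. A circular molecule with zero sites is
returned unchanged carrying an `"uncut"` note plus a logged warning.

Conservation is exact and tested: the summed per-strand nucleotide counts
of the fragments equal the parent's, and re-ligating the fragments of a
circular digest reproduces the input up to rotation.

## Ligation and insertion

Two ends ligate when both are blunt, or both are 5' overhangs of equal
length whose protruding sequences are reverse complements read 5'→3' on
their own strands — for the palindromic 4-nt overhangs here, sequence
equality. This makes BamHI/BglII and XbaI/SpeI isocaudamer pairs. Each
joint records a `Junction` with an 8-bp sealed window (the overhang plus
2 bp of context per side — enough to detect any 6-bp site) and the set of
enzymes that can recut it.

`insert_part` digests a circular backbone with two enzymes that must each
cut exactly once (more than one site means a malformed platform and is
refused), keeps the larger fragment (the standard's stuffer is discarded
implicitly; a `keep_label` override selects by annotation instead), and
ligates the insert in its unique compatible orientation — sticky-end
asymmetry (GATC vs CGCG) enforces orientation, and a part that fits zero
or two ways is refused. Only the designed single-insert product is
returned; self-ligation, concatemers and vector re-closure are real
ligation side products but out of scope. Product coordinates keep the
backbone's origin, and a backbone region feature that spanned both cut
points (the downstream standard region does) stretches across the insert;
features split by a single cut are dropped.

### Junction arithmetic of the part standard

With `A^GATCT` and `A^CGCGT` geometry the flanking `A` of both platform
sites leaves with the discarded stuffer. Two consequences follow, both
verified by the sealed-junction scans:

* the MluI entry site is regenerated if and only if the incoming part's
  top strand ends in `A` — the standard spacer (`ATCGTAA`) does;
* the BamHI/BglII fusion scar stays dead if and only if the operator does
  not begin with `T` (a leading `T` would re-create `AGATCT` right at the
  scar and give the product two BglII sites).

`design_downstream_part` enforces the standard's forbidden-site rule (no
site of the six downstream-relevant enzymes in or across the payloads
beyond the one designed BglII); the two junction rules above are surfaced
as advisory findings by `validate_downstream_part` and are built into the
randomized part generator, since they are consequences of the insertion
chemistry rather than properties of the isolated part. The spacer is
otherwise a free choice.

## The synthetic platform and parts

The platform plasmid is a synthetic stand-in whose engineered regulatory
region is fixed verbatim by the two published mutagenesis primers: the
upstream MCS is `GAATTC` plus the reverse complement of the BamSal primer
(yielding NotI–XbaI–SalI–BamHI in that order; NotI is present but not part
of the enzyme set), and the downstream standard region, RBS and start
codon are the BglMlu primer unchanged
(`GGAGATCT GTCGGATA ACGCGT GAGATTAAAGAGGAGAAATACTAG ATG`). The reporter
CDS (720 bp, a GFP-length placeholder) and vector filler (1500 bp standing
in for origin and marker, whose true sequence is not published) are
seeded pseudo-random DNA, rejection-sampled (bound: 1000 attempts) until
the whole 2313-bp circle carries exactly one site for each of the six
platform enzymes and none for SpeI. Same seed, same plasmid, byte for
byte.

The full map of the original platform vector is unpublished, which forces
one documented geometry decision. Taken literally, installing the Placq
promoter part by cutting SalI + the downstream BglII would destroy the
plasmid's only BglII site: the part's top strand ends in `C`, so the scar
(`...GCGCC GATCT...`) is cut by neither BamHI nor BglII, and the product
could never accept a downstream operator part — contradicting the
construct series the standard exists to support. The platform's MCS,
however, ends in a BamHI site directly abutting the downstream region, and
BamHI makes the identical `GATC` end. `insert_upstream` with the
(SalI, BglII) pair therefore cuts at SalI plus the GATC-class site inside
the MCS — here BamHI — discarding the SalI–BamHI stuffer and leaving the
downstream `GGAGATCT...ACGCGT` pair fully intact; on a platform without an
MCS GATC-class site it falls back to the downstream BglII (and says so in
the log). Every subsequent insertion then uses BglII + MluI literally. The
LuxR cassette enters by the (EcoRI, XbaI) route with an EcoRI/SpeI-ended
part: the EcoRI scar is regenerated, the XbaI/SpeI fusion scar is dead.

The LuxR cassette itself is a synthetic stand-in (the real Registry
fragment's sequence is not published and Registry retrieval is out of
scope): a fixed 244-nt literal with the correct AATT/CTAG end chemistry,
carrying the real 20-bp lux box operator (`ACCTGTAGGATCGTACAGGT`), a
placeholder expression-cassette segment, and a generic weak −35/−10
(`TTGACA...TATAAT`) standing in for luxpR. What passing tests show is that
the *standard* behaves as designed around these stand-ins; they say
nothing about the true vector or cassette sequences.

### Platform validation

Mandatory, always: exactly one BglII and one MluI inside the annotated
downstream region with BglII 5' of MluI; no BglII/MluI anywhere else; an
RBS annotation between the MluI site and the CDS start. The MCS site
checks (one each of EcoRI/XbaI/SalI/BamHI inside the MCS) are mandatory
only on a virgin platform: installing a promoter part legitimately
consumes entry sites (the XbaI site dies in the XbaI/SpeI scar; the MCS
BamHI is consumed by the Placq insertion, which happens to bring its own
internal BamHI), so post-insertion these checks are reported as advisory
rather than failing the construct. Uniqueness is thus interpreted
per-region, not globally.

## Boolean regulatory logic

The expression model is Boolean by design — the reported outcomes are
on/off states, and no kinetic model is available to fit, so inventing Hill
coefficients would manufacture precision:

```
output = polymerase_ok AND NOT repressed
polymerase_ok = strong
              | (weak AND activator available AND its inducer present)
repressed     = any repressor operator with regulator available
                AND its inducer absent
```

Regulator availability is one pool, whether the gene sits on the host
genome (strain configuration) or on the plasmid (expression-cassette
annotations). Operator position relative to the core is recorded but does
not affect the Boolean output, and tandem copies of one operator are
logically idempotent; both matter only for expression strength, which this
layer does not model. Truth tables enumerate all 2^n inducer combinations
(guarded at n ≤ 8) and are classified as
NULL / CONSTITUTIVE / BUFFER / NOT / AND / OR / OTHER, where for n > 2 AND
means ON only with everything present and OR means ON with anything
present. Two monotonicity properties follow from the two archetypes (both
induction modes are activating) and are property-tested: adding an inducer
never turns output off, and adding a repressor operator never grows the ON
set.

## Problem sizes and determinism

Default problem sizes: a 2313-bp platform, 100 randomized trials of
10-deep sequential insertion, 1000 random 2-kb molecules for the
restriction-engine cross-check, 500 random payloads for the design round
trip. The whole test suite and the acceptance script each run in seconds.
All randomness flows through explicit `random.Random(seed)` instances
(`random.Random` is stable across platforms); the acceptance script
derives its per-section seeds from `--seed`, and the pipeline is
byte-identical across runs at a fixed seed.

## Known limitations

* Quantitative expression (fold changes, leak, growth-phase effects) is
  explicitly out of scope; the Boolean layer cannot distinguish one lac
  operator from two.
* Only the two regulator archetypes are supported (inducer releases a
  repressor; inducer enables an activator); anything else is rejected.
* Ligation returns the designed product only; enumeration of side
  products is reserved for a future flag.
* The backbone filler and both cassette placeholders are synthetic;
  results transfer to the real vectors only insofar as those share the
  engineered regulatory region, which is the part the primers pin down.
* GenBank/FASTA cannot represent sticky ends natively; the toolkit round-
  trips them through description tokens, which other software will ignore.
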