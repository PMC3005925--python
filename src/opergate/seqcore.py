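"""Exact double-stranded DNA representation: strands, sticky ends, motif search.

Conventions
-----------
* Coordinates are 0-based, half-open, on the top strand.
* Circular molecules have a fixed origin chosen at construction and carry no
  ends; positions are reported in ``[0, length)``.
* Only the strict alphabet ``A/C/G/T`` is accepted. IUPAC ambiguity codes are
  rejected rather than expanded so that digestion and ligation semantics stay
  exact — every sequence handled here is fully specified.
* A :class:`StickyEnd` overhang is written 5'→3' on the protruding strand.
  For the 5'-overhang chemistry supported throughout, a left end can only
  protrude on the top strand and a right end only on the bottom strand; 3'
  overhangs are representable (``kind="three_prime"``) but no operation
  accepts them.

The top strand of a linear :class:`DuplexFragment` holds *all* top-strand
nucleotides, including a top-protruding left overhang. Bottom-strand-only
bases (a right 5' overhang) live solely in the end descriptor; the full
bottom strand is derived on demand.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterator

from Bio.Seq import Seq

from .errors import (
    AmbiguousAlignmentError,
    AnnealingError,
    SequenceAlphabetError,
    UnsupportedEndError,
)

ALPHABET = frozenset("ACGT")

#: Shortest duplex treated as an annealed state (the 4-nt sticky ends in
#: scope are the shortest stable pairing the toolkit reasons about).
MIN_DUPLEX = 4

#: End kinds. ``three_prime`` is reserved: representable, rejected by all
#: assembly operations (no enzyme in scope produces 3' overhangs).
BLUNT_KIND = "blunt"
FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"

LINEAR = "linear"
CIRCULAR = "circular"

#: Feature role vocabulary shared across the toolkit.
FEATURE_ROLES = (
    "mcs_upstream",
    "downstream_region",
    "rbs",
    "cds",
    "operator",
    "promoter_core",
    "expression_cassette",
)


def as_nuc(seq: str, *, context: str = "sequence") -> str:
    """Validate and normalise *seq* to an uppercase A/C/G/T string."""
    if not isinstance(seq, str):
        raise SequenceAlphabetError(f"{context}: expected str, got {type(seq).__name__}")
    s = seq.upper()
    bad = set(s) - ALPHABET
    if bad:
        raise SequenceAlphabetError(
            f"{context}: characters outside ACGT: {sorted(bad)!r} (ambiguity codes are rejected)"
        )
    return s


def reverse_complement(seq: str) -> str:
    """Watson–Crick reverse complement. An involution on valid input."""
    return str(Seq(as_nuc(seq)).reverse_complement())


@dataclass(frozen=True)
class StickyEnd:
    """Terminus of a linear duplex: blunt or a 5' overhang.

    ``overhang`` is read 5'→3' on the protruding strand; ``strand`` records
    which strand protrudes (``"top"``/``"bottom"``/``"none"``).
    """

    kind: str = BLUNT_KIND
    overhang: str = ""
    strand: str = "none"

    def __post_init__(self) -> None:
        if self.kind not in (BLUNT_KIND, FIVE_PRIME, THREE_PRIME):
            raise UnsupportedEndError(f"unknown end kind {self.kind!r}")
        if self.kind == BLUNT_KIND:
            if self.overhang or self.strand != "none":
                raise UnsupportedEndError("blunt ends carry no overhang")
        else:
            if not self.overhang:
                raise UnsupportedEndError(f"{self.kind} end requires a non-empty overhang")
            object.__setattr__(self, "overhang", as_nuc(self.overhang, context="overhang"))
            if self.strand not in ("top", "bottom"):
                raise UnsupportedEndError("overhanging end must name the protruding strand")

    @property
    def is_blunt(self) -> bool:
        return self.kind == BLUNT_KIND

    def __len__(self) -> int:
        return len(self.overhang)


BLUNT = StickyEnd()


@dataclass
class Feature:
    """A labelled span on the top strand, ``[start, end)``."""

    label: str
    start: int
    end: int
    role: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.role not in FEATURE_ROLES:
            raise ValueError(f"unknown feature role {self.role!r}; expected one of {FEATURE_ROLES}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"feature {self.label!r}: invalid span [{self.start}, {self.end})")

    def shifted(self, delta: int, modulo: int | None = None) -> "Feature":
        s, e = self.start + delta, self.end + delta
        if modulo is not None:
            s %= modulo
            e = s + (self.end - self.start)
        return Feature(self.label, s, e, self.role, dict(self.meta))


@dataclass
class Junction:
    """Record of one ligation joint.

    ``sealed_sequence`` is the top-strand window spanning the joint: the
    4-nt overhang plus up to 2 bp of context on each side (shorter only at a
    linear molecule's extremity). ``recuttable_by`` lists enzymes whose
    recognition site survives (or is created) inside that window.
    """

    left_parent: str
    right_parent: str
    sealed_sequence: str
    recuttable_by: frozenset[str] = frozenset()
    position: int | None = None


@dataclass
class DuplexFragment:
    """A double-stranded DNA molecule, linear or circular.

    For linear molecules, ``top`` is the complete top strand 5'→3' (including
    a top-protruding left overhang); ``left_end``/``right_end`` describe the
    termini. Circular molecules carry ``left_end = right_end = None``.
    """

    top: str
    topology: str = LINEAR
    left_end: StickyEnd | None = BLUNT
    right_end: StickyEnd | None = BLUNT
    features: list[Feature] = field(default_factory=list)
    junctions: list[Junction] = field(default_factory=list)
    name: str = ""
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.top = as_nuc(self.top, context=f"fragment {self.name or '<anon>'}")
        if self.topology not in (LINEAR, CIRCULAR):
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.topology == CIRCULAR:
            if self.left_end is not None or self.right_end is not None:
                raise ValueError("circular molecules have no ends")
        else:
            if self.left_end is None or self.right_end is None:
                raise ValueError("linear molecules require both end descriptors")
            le, re_ = self.left_end, self.right_end
            if le.kind == FIVE_PRIME and le.strand != "top":
                raise UnsupportedEndError("a left 5' overhang protrudes on the top strand")
            if re_.kind == FIVE_PRIME and re_.strand != "bottom":
                raise UnsupportedEndError("a right 5' overhang protrudes on the bottom strand")
            if le.kind == THREE_PRIME and le.strand != "bottom":
                raise UnsupportedEndError("a left 3' overhang protrudes on the bottom strand")
            if re_.kind == THREE_PRIME and re_.strand != "top":
                raise UnsupportedEndError("a right 3' overhang protrudes on the top strand")
            if le.strand == "top" and not self.top.startswith(le.overhang):
                raise ValueError("left overhang bases must open the top strand")
            if re_.strand == "top" and not self.top.endswith(re_.overhang):
                raise ValueError("right 3' overhang bases must close the top strand")
            if len(self.core_top) < 1:
                raise ValueError("fragment must retain at least one double-stranded base pair")

    # -- geometry -----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.top)

    @property
    def is_circular(self) -> bool:
        return self.topology == CIRCULAR

    @property
    def _ss_left_top(self) -> int:
        if self.is_circular:
            return 0
        return len(self.left_end) if self.left_end.strand == "top" else 0

    @property
    def _ss_right_top(self) -> int:
        if self.is_circular:
            return 0
        return len(self.right_end) if self.right_end.strand == "top" else 0

    @property
    def core_top(self) -> str:
        """Top strand of the fully double-stranded core."""
        if self.is_circular:
            return self.top
        end = len(self.top) - self._ss_right_top
        return self.top[self._ss_left_top : end]

    @property
    def bottom(self) -> str:
        """The full bottom strand, 5'→3'."""
        if self.is_circular:
            return reverse_complement(self.top)
        right_part = self.right_end.overhang if self.right_end.strand == "bottom" else ""
        left_part = self.left_end.overhang if self.left_end.strand == "bottom" else ""
        return right_part + reverse_complement(self.core_top) + left_part

    @property
    def total_nt(self) -> int:
        """Total nucleotide count over both strands (conserved by digestion)."""
        return len(self.top) + len(self.bottom)

    def duplex_bounds(self) -> tuple[int, int]:
        """Top-strand span ``[a, b)`` that is double-stranded."""
        if self.is_circular:
            return 0, len(self.top)
        return self._ss_left_top, len(self.top) - self._ss_right_top

    # -- transforms ---------------------------------------------------------

    def rotated(self, new_origin: int) -> "DuplexFragment":
        """Return the circular molecule with its origin moved to *new_origin*."""
        if not self.is_circular:
            raise ValueError("only circular molecules can be rotated")
        n = len(self.top)
        o = new_origin % n
        feats = [f.shifted(-o, modulo=n) for f in self.features]
        return DuplexFragment(
            self.top[o:] + self.top[:o],
            CIRCULAR,
            None,
            None,
            feats,
            list(self.junctions),
            self.name,
            list(self.notes),
        )

    def flipped(self) -> "DuplexFragment":
        """Return the molecule read from the other strand (reverse complement).

        Ends swap sides; a right bottom-protruding 5' overhang becomes a left
        top-protruding one with the same 5'→3' sequence.
        """
        if self.is_circular:
            n = len(self.top)
            feats = [
                Feature(f.label, n - f.end, n - f.start, f.role, dict(f.meta))
                for f in self.features
            ]
            return DuplexFragment(
                reverse_complement(self.top), CIRCULAR, None, None, feats, [], self.name
            )
        new_top = self.bottom
        flip_strand = {"top": "bottom", "bottom": "top", "none": "none"}
        new_left = replace(self.right_end, strand=flip_strand[self.right_end.strand])
        new_right = replace(self.left_end, strand=flip_strand[self.left_end.strand])
        # Map top-strand feature spans through molecule columns mirrored left-right.
        lt = len(self.top)
        lb = len(new_top)
        tl = len(self.left_end) if self.left_end.strand == "bottom" else 0  # top col offset
        bl = len(self.left_end) if self.left_end.strand == "top" else 0  # bottom col offset
        feats = []
        for f in self.features:
            ns = bl + lb - tl - f.end
            ne = bl + lb - tl - f.start
            if 0 <= ns < ne <= lb:
                feats.append(Feature(f.label, ns, ne, f.role, dict(f.meta)))
        return DuplexFragment(new_top, LINEAR, new_left, new_right, feats, [], self.name)

    def features_by_role(self, role: str) -> list[Feature]:
        return sorted((f for f in self.features if f.role == role), key=lambda f: f.start)

    def slice_top(self, start: int, end: int) -> str:
        """Top-strand substring, crossing the origin on circular molecules."""
        n = len(self.top)
        if self.is_circular:
            start %= n
            end = end % n or (n if end else 0)
            if end > start:
                return self.top[start:end]
            return self.top[start:] + self.top[:end]
        return self.top[start:end]


# -- operations -------------------------------------------------------------


def anneal_oligos(top_oligo: str, bottom_oligo: str, *, name: str = "") -> DuplexFragment:
    """Anneal two oligos into a linear duplex with blunt or 5'-overhang ends.

    The oligos must admit exactly one ungapped antiparallel alignment that
    pairs at least :data:`MIN_DUPLEX` bases, with every paired position
    Watson–Crick complementary and unpaired positions occurring only as
    terminal 5' extensions. Shorter chance complementarities (1-3 bp, which
    almost any oligo pair exhibits at its extremities) are below the
    shortest sticky end in scope and are not counted as annealed states.
    Internal mismatches or no valid alignment raise an annealing error;
    several valid alignments raise an ambiguity error rather than guess —
    a silent choice could build the wrong part.
    """
    top = as_nuc(top_oligo, context="top oligo")
    bottom = as_nuc(bottom_oligo, context="bottom oligo")
    rcb = reverse_complement(bottom)
    hits: list[int] = []
    # Offset d places rcb d bases to the right of the top 5' end. Valid
    # alignments leave only 5' extensions: d >= 0 (top 5' extension) and the
    # rcb tail reaching at least the top 3' end (bottom 5' extension).
    for d in range(len(top) - MIN_DUPLEX + 1):
        overlap = len(top) - d
        if overlap > len(rcb):
            continue  # top 3' tail would dangle: a 3' extension, not allowed
        if top[d:] == rcb[:overlap]:
            hits.append(d)
    if not hits:
        raise AnnealingError(
            "no valid ungapped antiparallel alignment (internal mismatch or 3' extension)"
        )
    if len(hits) > 1:
        raise AmbiguousAlignmentError(
            f"{len(hits)} valid alignments (offsets {hits}); refusing to guess"
        )
    d = hits[0]
    e = d + len(rcb) - len(top)  # bottom 5' extension length
    left = StickyEnd(FIVE_PRIME, top[:d], "top") if d else BLUNT
    right = StickyEnd(FIVE_PRIME, bottom[:e], "bottom") if e else BLUNT
    return DuplexFragment(top, LINEAR, left, right, name=name)


def find_motif(molecule: DuplexFragment, motif: str) -> list[tuple[int, str]]:
    """All top-strand start positions where *motif* occurs on either strand.

    Returns ``(position, strand)`` pairs sorted by position; a palindromic
    motif at one locus is reported once, as a top-strand hit. Circular
    molecules are scanned across the origin. Bottom-strand hits are reported
    at the top-strand start of their reverse-complement window.
    """
    m = as_nuc(motif, context="motif")
    if not m:
        raise ValueError("motif must be non-empty")
    rc = reverse_complement(m)
    hits: dict[tuple[int, str], None] = {}
    for query, strand in ((m, "top"), (rc, "bottom")):
        if strand == "bottom" and rc == m:
            continue  # palindrome: one report per locus
        for pos in _scan(molecule, query):
            hits[(pos, strand)] = None
    return sorted(hits)


def _scan(molecule: DuplexFragment, query: str) -> Iterator[int]:
    n = len(molecule.top)
    if molecule.is_circular:
        text = molecule.top + molecule.top[: len(query) - 1]
    else:
        text = molecule.top
    start = 0
    while True:
        i = text.find(query, start)
        if i == -1:
            return
        yield i % n
        start = i + 1


def fragments_equal_up_to_rotation(a: DuplexFragment, b: DuplexFragment) -> bool:
    """True if two circular molecules have the same sequence up to origin choice."""
    if not (a.is_circular and b.is_circular) or len(a.top) != len(b.top):
        return False
    return b.top in (a.top + a.top)
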