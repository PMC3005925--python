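"""Strand arithmetic, annealing geometry and motif search."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from opergate import DuplexFragment, anneal_oligos, find_motif, reverse_complement
from opergate.errors import (
    AmbiguousAlignmentError,
    AnnealingError,
    SequenceAlphabetError,
)
from opergate.seqcore import CIRCULAR, StickyEnd

from .conftest import random_seq

dna = st.text(alphabet="ACGT", min_size=1, max_size=200)


@pytest.mark.parametrize(
    ("seq", "expected"),
    [
        ("GGATCC", "GGATCC"),  # palindrome
        ("ACGCGT", "ACGCGT"),  # palindrome
        ("GATCGG", "CCGATC"),  # per-base complement then reverse
    ],
)
def test_reverse_complement_examples(seq, expected):
    assert reverse_complement(seq) == expected


@settings(derandomize=True)
@given(dna)
def test_reverse_complement_is_an_involution(seq):
    assert reverse_complement(reverse_complement(seq)) == seq


def test_invalid_alphabet_rejected():
    with pytest.raises(SequenceAlphabetError):
        reverse_complement("GANTC")
    with pytest.raises(SequenceAlphabetError):
        DuplexFragment("ACGN")


@pytest.mark.parametrize(
    ("top", "bottom", "core_len", "left", "right"),
    [
        (  # synthesized LacI operator part oligos
            "GATCGGAATTGTGAGCGGATAACAATTCCAGATCTATCGTAA",
            "CGCGTTACGATAGATCTGGAATTGTTATCCGCTCACAATTCC",
            38, ("GATC", "top"), ("CGCG", "bottom"),
        ),
        (  # synthesized Placq promoter-part oligos
            "TCGACCGTGACGGATCCTGGTGCAAAACCTTTCGCGGTATGGCATGATAGCGCC",
            "GATCGGCGCTATCATGCCATACCGCGAAAGGTTTTGCACCAGGATCCGTCACGG",
            50, ("TCGA", "top"), ("GATC", "bottom"),
        ),
        ("GAATTC", "GAATTC", 6, None, None),  # self-complementary palindrome, blunt
    ],
)
def test_anneal_oligos_end_structure(top, bottom, core_len, left, right):
    frag = anneal_oligos(top, bottom)
    assert len(frag.core_top) == core_len
    if left is None:
        assert frag.left_end.is_blunt and frag.right_end.is_blunt
    else:
        assert (frag.left_end.overhang, frag.left_end.strand) == left
        assert (frag.right_end.overhang, frag.right_end.strand) == right
    # the duplex must reconstruct both input oligos exactly
    assert frag.top == top
    assert frag.bottom == bottom


def test_anneal_rejects_internal_mismatch():
    with pytest.raises(AnnealingError):
        anneal_oligos("GATCAAAACCCC", "GGGGTTTA")


def test_anneal_rejects_three_prime_extension():
    # complementary core but the top strand dangles at its 3' end
    with pytest.raises(AnnealingError):
        anneal_oligos("AACCGGTTAAAA", "AACCGGTT")


def test_anneal_refuses_ambiguous_palindromic_oligos():
    # both a blunt 8-bp state and a 4-nt-overhang state exist
    with pytest.raises(AmbiguousAlignmentError):
        anneal_oligos("GATCGATC", "GATCGATC")


@settings(derandomize=True, max_examples=200)
@given(core=st.text(alphabet="ACGT", min_size=6, max_size=60),
       left=st.text(alphabet="ACGT", min_size=0, max_size=6),
       right=st.text(alphabet="ACGT", min_size=0, max_size=6))
def test_anneal_reconstructs_constructed_duplexes(core, left, right):
    """Oligos built from (left 5' ext + core) / (right 5' ext + rc(core))
    either anneal back to exactly that geometry or refuse as ambiguous."""
    top = left + core
    bottom = right + reverse_complement(core)
    try:
        frag = anneal_oligos(top, bottom)
    except AmbiguousAlignmentError:
        return  # chance alternative alignment: refusal is the contract
    assert frag.top == top
    assert frag.bottom == bottom


# -- motif search -----------------------------------------------------------

PRIMER = "GGAGATCTGTCGGATAACGCGTGAGATTAAAGAGGAGAAATACTAGATG"


@pytest.mark.parametrize(
    ("motif", "expected"),
    [
        ("AGATCT", [(2, "top")]),
        ("ACGCGT", [(16, "top")]),
        ("AAAAAA", []),
    ],
)
def test_find_motif_on_engineered_region(motif, expected):
    assert find_motif(DuplexFragment(PRIMER), motif) == expected


def test_find_motif_reports_bottom_strand_hits():
    # the bottom strand of AAGGTACAAA reads TTTGTACCTT and carries TGTACC
    mol = DuplexFragment("AAGGTACAAA")
    assert find_motif(mol, "TGTACC") == [(2, "bottom")]


def test_find_motif_crosses_circular_origin():
    mol = DuplexFragment("TCTAAAAAGA", CIRCULAR, None, None)
    # AGATCT? no; use motif spanning the origin: last 3 + first 3 = AGA+TCT
    assert (7, "top") in find_motif(mol, "AGATCT")


def naive_find(top, motif, circular):
    """Quadratic double-strand window scan, the independent oracle."""
    rc = reverse_complement(motif)
    n = len(top)
    text = top + (top[: len(motif) - 1] if circular else "")
    hits = set()
    for i in range(len(text) - len(motif) + 1):
        w = text[i : i + len(motif)]
        if w == motif:
            hits.add((i % n, "top"))
        if w == rc and rc != motif:
            hits.add((i % n, "bottom"))
    return sorted(hits)


@pytest.mark.parametrize("circular", [False, True])
def test_find_motif_agrees_with_naive_scan(rng, circular):
    for _ in range(40):
        n = rng.randint(20, 300)
        top = random_seq(rng, n)
        motif = random_seq(rng, rng.randint(2, 6))
        mol = (DuplexFragment(top, CIRCULAR, None, None) if circular
               else DuplexFragment(top))
        assert find_motif(mol, motif) == naive_find(top, motif, circular)


def test_sticky_end_validation():
    with pytest.raises(Exception):
        StickyEnd("five_prime", "", "top")  # overhang required
    with pytest.raises(Exception):
        StickyEnd("blunt", "GATC", "top")  # blunt carries no overhang
    end = StickyEnd("five_prime", "gatc", "top")
    assert end.overhang == "GATC"


def test_flip_swaps_ends_and_preserves_strands(lac_part):
    frag = lac_part.fragment
    flipped = frag.flipped()
    assert (flipped.left_end.overhang, flipped.left_end.strand) == ("CGCG", "top")
    assert (flipped.right_end.overhang, flipped.right_end.strand) == ("GATC", "bottom")
    assert flipped.top == frag.bottom and flipped.bottom == frag.top
    back = flipped.flipped()
    assert back.top == frag.top
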