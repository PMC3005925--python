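"""Sticky-end compatibility, ligation and the standardized insertion operation.

Two 5' overhangs ligate when their protruding sequences are reverse
complements read 5'→3' on their respective strands; for the palindromic
4-nt overhangs in scope this reduces to sequence equality. This is what
makes BamHI/BglII and XbaI/SpeI isocaudamer pairs: different recognition
sites, identical overhangs, and a fusion scar that neither enzyme recuts —
the trick that lets a part be inserted repeatedly between already-joined
parts.

Only the designed single-insert product is returned by :func:`insert_part`;
self-ligation, concatemers and vector re-closure (real side products of a
ligation mix) are not enumerated.
"""

from __future__ import annotations

import logging

from .enzymes import Enzyme, builtin_enzymes, digest, find_sites
from .errors import (
    AmbiguousSiteError,
    LigationError,
    OrientationError,
    UnsupportedEndError,
)
from .seqcore import (
    CIRCULAR,
    LINEAR,
    THREE_PRIME,
    DuplexFragment,
    Feature,
    Junction,
    StickyEnd,
    fragments_equal_up_to_rotation,
    reverse_complement,
)

log = logging.getLogger(__name__)

#: Top-strand context kept on each side of the 4-nt overhang in a sealed
#: junction window: enough to detect every 6-bp site in scope.
JUNCTION_CONTEXT = 2


def ends_compatible(a: StickyEnd, b: StickyEnd) -> bool:
    """Can a right end *a* ligate to a left end *b*?

    True iff both blunt, or both 5' overhangs of equal length whose
    protruding sequences are reverse complements when read 5'→3' on their
    respective protruding strands.
    """
    if a.kind == THREE_PRIME or b.kind == THREE_PRIME:
        raise UnsupportedEndError("3' overhangs are not supported by ligation")
    if a.is_blunt and b.is_blunt:
        return True
    if a.is_blunt or b.is_blunt:
        return False
    return len(a) == len(b) and reverse_complement(a.overhang) == b.overhang


def _junction(top: str, pos: int, overhang_len: int, circular: bool,
              left_name: str, right_name: str) -> Junction:
    n = len(top)
    if circular:
        lo = pos - JUNCTION_CONTEXT
        hi = pos + overhang_len + JUNCTION_CONTEXT
        window = "".join(top[i % n] for i in range(lo, hi))
    else:
        lo = max(0, pos - JUNCTION_CONTEXT)
        hi = min(n, pos + overhang_len + JUNCTION_CONTEXT)
        window = top[lo:hi]
    cutters = frozenset(
        enz.name for enz in builtin_enzymes()
        if enz.recognition in window or reverse_complement(enz.recognition) in window
    )
    return Junction(left_name, right_name, window, cutters, pos % n if n else pos)


def ligate(fragments: list[DuplexFragment], circularize: bool = False) -> DuplexFragment:
    """Seal an ordered run of fragments into one molecule.

    Each adjacent pair (and last-to-first when circularizing) must have
    compatible ends. The joined top strand is the concatenation of the
    fragment top strands — each shared overhang is written once, because a
    right-end overhang lives on the bottom strand and its partner opens the
    next fragment's top strand. One :class:`Junction` is recorded per joint.
    """
    if not fragments:
        raise LigationError("nothing to ligate")
    if len(fragments) == 1 and not circularize:
        raise LigationError("a single fragment requires circularize=True to change")
    pairs = list(zip(fragments, fragments[1:]))
    if circularize:
        pairs.append((fragments[-1], fragments[0]))
    for k, (a, b) in enumerate(pairs):
        if a.is_circular or b.is_circular:
            raise LigationError("circular molecules cannot be ligated")
        if not ends_compatible(a.right_end, b.left_end):
            raise LigationError(
                f"incompatible joint {k}: {a.name or '<anon>'} right end "
                f"{a.right_end.kind}:{a.right_end.overhang or '-'} vs "
                f"{b.name or '<anon>'} left end {b.left_end.kind}:{b.left_end.overhang or '-'}"
            )
    top = "".join(f.top for f in fragments)
    feats: list[Feature] = []
    offset = 0
    offsets = []
    for f in fragments:
        offsets.append(offset)
        feats.extend(ft.shifted(offset) for ft in f.features)
        offset += len(f.top)
    junctions = []
    for k in range(1, len(fragments)):
        a, b = fragments[k - 1], fragments[k]
        # b's top opens with its left overhang, so the sealed window starts there
        junctions.append(_junction(top, offsets[k], len(b.left_end), circularize,
                                   a.name, b.name))
    if circularize:
        a, b = fragments[-1], fragments[0]
        junctions.append(_junction(top, 0, len(b.left_end), True, a.name, b.name))
        return DuplexFragment(top, CIRCULAR, None, None, feats, junctions,
                              name="+".join(f.name for f in fragments if f.name))
    return DuplexFragment(top, LINEAR, fragments[0].left_end, fragments[-1].right_end,
                          feats, junctions,
                          name="+".join(f.name for f in fragments if f.name))


def insert_part(
    backbone: DuplexFragment,
    part: DuplexFragment,
    backbone_enzymes: tuple[Enzyme, Enzyme],
    *,
    keep_label: str | None = None,
) -> DuplexFragment:
    """Digest a circular backbone with two single-cutters, drop the stuffer,
    ligate *part* in its unique compatible orientation and re-circularize.

    Retains the larger digestion fragment by default (the standard's small
    stuffer is discarded implicitly); ``keep_label`` overrides retention by
    annotation label. Backbone annotations are preserved with recomputed
    coordinates — a region feature that spanned both cut points stretches
    over the insert — and the part's annotations are added. Coordinates keep
    the backbone's origin when the stuffer does not contain it.
    """
    if not backbone.is_circular:
        raise ValueError("insert_part expects a circular backbone")
    enz_a, enz_b = backbone_enzymes
    for enz in (enz_a, enz_b):
        n_sites = len(find_sites(backbone, enz))
        if n_sites == 0:
            raise AmbiguousSiteError(f"{enz.name}: no site on backbone {backbone.name!r}")
        if n_sites > 1:
            raise AmbiguousSiteError(
                f"{enz.name}: {n_sites} sites on backbone {backbone.name!r}; the standard "
                "guarantees uniqueness — refusing a malformed platform"
            )
    frags = digest(backbone, {enz_a, enz_b})
    assert len(frags) == 2
    if keep_label is not None:
        keep = [f for f in frags if any(ft.label == keep_label for ft in f.features)]
        if len(keep) != 1:
            raise ValueError(f"keep_label {keep_label!r} does not select exactly one fragment")
        kept = keep[0]
    else:
        kept = max(frags, key=lambda f: len(f.top))
    stuffer = frags[0] if kept is frags[1] else frags[1]

    orientations = []
    for cand, tag in ((part, "as-given"), (part.flipped(), "flipped")):
        if ends_compatible(kept.right_end, cand.left_end) and ends_compatible(
            cand.right_end, kept.left_end
        ):
            orientations.append((cand, tag))
    if len(orientations) != 1:
        raise OrientationError(
            f"part {part.name!r} fits the cut backbone in {len(orientations)} orientations "
            "(need exactly one: sticky-end asymmetry must enforce it)"
        )
    oriented, tag = orientations[0]
    if tag == "flipped":
        log.info("insert_part: part %s inserted in flipped orientation", part.name or "<anon>")

    product = ligate([kept, oriented], circularize=True)

    # Recompute coordinates against the backbone origin. The stuffer occupies
    # top-strand span [cs, cs + len) on the backbone, located from the two cut
    # coordinates (never by string search: the stuffer text may recur).
    n = len(backbone.top)
    cut_a = (find_sites(backbone, enz_a).positions[0] + enz_a.cut_offset_top) % n
    cut_b = (find_sites(backbone, enz_b).positions[0] + enz_b.cut_offset_top) % n
    s_len = len(stuffer.top)
    if (cut_b - cut_a) % n == s_len and backbone.slice_top(cut_a, cut_b) == stuffer.top:
        cs = cut_a
    else:
        cs = cut_b
    delta = len(oriented.top) - s_len
    if cs + s_len <= n:  # stuffer does not wrap the origin
        ce = cs + s_len
        direct_top = backbone.top[:cs] + oriented.top + backbone.top[ce:]
        feats: list[Feature] = []
        for f in backbone.features:
            if f.end <= cs:
                feats.append(f.shifted(0))
            elif f.start >= ce:
                feats.append(f.shifted(delta))
            elif f.start <= cs and f.end >= ce:
                feats.append(Feature(f.label, f.start, f.end + delta, f.role, dict(f.meta)))
            # features split by a cut are dropped
        feats.extend(f.shifted(cs) for f in oriented.features)
        if not fragments_equal_up_to_rotation(
            product, DuplexFragment(direct_top, CIRCULAR, None, None)
        ):  # pragma: no cover - internal consistency guard
            raise AssertionError("ligation product disagrees with direct construction")
        # Junctions from ligate are in kept-fragment coordinates; in backbone
        # coordinates the part's left overhang sits at cs and the resealed
        # backbone head at cs + len(part top).
        jmap = (cs, (cs + len(oriented.top)) % len(direct_top))
        junctions = [
            Junction(j.left_parent, j.right_parent, j.sealed_sequence, j.recuttable_by, p)
            for j, p in zip(product.junctions, jmap)
        ]
        return DuplexFragment(direct_top, CIRCULAR, None, None, feats,
                              junctions, name=product.name)
    # Stuffer wraps the backbone origin: keep the ligation product's own
    # coordinates (origin at the kept fragment's first base).
    return product
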