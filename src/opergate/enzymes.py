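"""Type-II restriction enzymes and digestion of linear/circular molecules.

The seven enzymes in scope (EcoRI, XbaI, SalI, BamHI, BglII, MluI, SpeI)
are all palindromic 6-cutters leaving 4-nt 5' overhangs. Their geometries
live in a versioned YAML data file (``data/enzymes.yaml``) and can be
overridden with a user table of the same shape.

Digestion is complete: every accessible site is cut. A recognition site
whose span would extend into a single-stranded overhang of a linear
fragment is not reported — the enzyme needs duplex DNA. Dam/Dcm
methylation sensitivity, star activity and kinetics are out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .errors import ParseError
from .seqcore import (
    CIRCULAR,
    FIVE_PRIME,
    LINEAR,
    BLUNT,
    DuplexFragment,
    StickyEnd,
    as_nuc,
    reverse_complement,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Enzyme:
    """A palindromic type-II restriction enzyme producing a 5' overhang."""

    name: str
    recognition: str
    cut_offset_top: int

    def __post_init__(self) -> None:
        rec = as_nuc(self.recognition, context=f"{self.name} recognition")
        object.__setattr__(self, "recognition", rec)
        if not 6 <= len(rec) <= 8:
            raise ValueError(f"{self.name}: recognition length {len(rec)} outside 6-8")
        if rec != reverse_complement(rec):
            raise ValueError(f"{self.name}: recognition {rec} is not palindromic")
        if not 0 <= self.cut_offset_top < len(rec) / 2:
            raise ValueError(
                f"{self.name}: cut offset {self.cut_offset_top} does not give a 5' overhang"
            )

    @property
    def overhang_len(self) -> int:
        return len(self.recognition) - 2 * self.cut_offset_top

    @property
    def overhang(self) -> str:
        """The 5' overhang sequence, 5'→3' on the protruding strand."""
        return self.recognition[self.cut_offset_top : len(self.recognition) - self.cut_offset_top]


@dataclass
class SiteList:
    """Sorted recognition-start positions of one enzyme on one molecule."""

    enzyme: Enzyme
    positions: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.positions)


def load_enzymes(path: str | Path | None = None) -> dict[str, Enzyme]:
    """Load an enzyme table, by default the packaged versioned one."""
    if path is None:
        text = resources.files("opergate.data").joinpath("enzymes.yaml").read_text()
    else:
        text = Path(path).read_text()
    try:
        doc = yaml.safe_load(text)
        entries = doc["enzymes"]
    except Exception as exc:  # noqa: BLE001 - rewrap with context
        raise ParseError(f"malformed enzyme table: {exc}") from exc
    table = {}
    for e in entries:
        enz = Enzyme(e["name"], e["recognition"], int(e["cut_offset_top"]))
        if enz.name in table:
            raise ParseError(f"duplicate enzyme name {enz.name}")
        table[enz.name] = enz
    return table


_BUILTIN: dict[str, Enzyme] | None = None


def builtin_enzymes() -> list[Enzyme]:
    """The seven enzymes of the standard, from the packaged table."""
    global _BUILTIN
    if _BUILTIN is None:
        _BUILTIN = load_enzymes()
    return list(_BUILTIN.values())


def lookup(name: str) -> Enzyme:
    for enz in builtin_enzymes():
        if enz.name.lower() == name.lower():
            return enz
    raise KeyError(f"no built-in enzyme named {name!r}")


def find_sites(molecule: DuplexFragment, enzyme: Enzyme) -> SiteList:
    """All recognition loci of *enzyme* on *molecule*.

    Palindromic recognition means one locus per double-stranded occurrence.
    Circular scans cross the origin. On linear fragments, loci must lie
    entirely inside the double-stranded region.
    """
    rec = enzyme.recognition
    n = len(molecule.top)
    text = molecule.top + (molecule.top[: len(rec) - 1] if molecule.is_circular else "")
    lo, hi = molecule.duplex_bounds()
    positions = []
    start = 0
    while True:
        i = text.find(rec, start)
        if i == -1:
            break
        start = i + 1
        if not molecule.is_circular and not (lo <= i and i + len(rec) <= hi):
            continue  # recognition extends into a single-stranded overhang
        positions.append(i % n)
    return SiteList(enzyme, sorted(set(positions)))


def digest(molecule: DuplexFragment, enzymes: set[Enzyme] | list[Enzyme]) -> list[DuplexFragment]:
    """Cut *molecule* at every accessible site of every enzyme.

    Digestion is complete, but a site is only cuttable on duplex DNA: when
    two sites overlap so closely that one cut would land inside the
    single-stranded overhang left by the other, the leftmost-from-origin
    cut wins and the blocked site survives uncut in the product.

    A circular molecule with k total cuts yields k linear fragments, a
    linear one k+1, each new end carrying the cutting enzyme's 5' overhang.
    Fragments are returned in top-strand order from the origin. Total
    nucleotide count per strand is conserved.

    A circular molecule with zero sites is returned unchanged with a
    ``"uncut"`` note (no cut occurred).
    """
    enzymes = list(enzymes)
    if not enzymes:
        raise ValueError("enzyme set must be non-empty")
    n = len(molecule.top)
    sites: list[tuple[int, Enzyme]] = []  # (recognition start, enzyme)
    for enz in enzymes:
        for p in find_sites(molecule, enz).positions:
            sites.append((p, enz))
    sites.sort(key=lambda s: s[0])
    # A site whose recognition would land in the single-stranded overhang
    # left by the previous (leftmost-first) cut is blocked: the enzyme needs
    # duplex DNA, so overlapping sites cannot all be cut and the blocked one
    # survives in the product.
    accepted: list[tuple[int, int, Enzyme]] = []  # (site start, unwrapped cut, enzyme)
    for p, enz in sites:
        if accepted:
            _, c_prev, e_prev = accepted[-1]
            if p < c_prev + e_prev.overhang_len:
                log.info("digest: %s site at %d blocked by the cut at %d", enz.name, p, c_prev)
                continue
        accepted.append((p, p + enz.cut_offset_top, enz))
    if molecule.is_circular and len(accepted) >= 2:
        # the same accessibility rule applies across the origin between the
        # last accepted cut and the first accepted site
        while len(accepted) >= 2:
            _, c_last, e_last = accepted[-1]
            p_first = accepted[0][0]
            if (p_first - c_last) % n >= e_last.overhang_len:
                break
            log.info("digest: dropping wrap-blocked cut at %d", c_last % n)
            accepted.pop()
    cuts = sorted((c % n, enz) for _, c, enz in accepted)
    if not cuts:
        if molecule.is_circular:
            log.warning("digest: no site for %s on %s; molecule returned uncut",
                        [e.name for e in enzymes], molecule.name or "<anon>")
            out = DuplexFragment(
                molecule.top, CIRCULAR, None, None,
                [f.shifted(0) for f in molecule.features], name=molecule.name,
                notes=molecule.notes + ["uncut"],
            )
            return [out]
        return [_copy_linear(molecule)]

    if molecule.is_circular:
        return [_circular_fragment(molecule, cuts, i) for i in range(len(cuts))]
    return _linear_fragments(molecule, cuts)


def _copy_linear(m: DuplexFragment) -> DuplexFragment:
    return DuplexFragment(m.top, LINEAR, m.left_end, m.right_end,
                          [f.shifted(0) for f in m.features], name=m.name)


def _sticky(enz: Enzyme, strand: str) -> StickyEnd:
    return StickyEnd(FIVE_PRIME, enz.overhang, strand)


def _circular_fragment(m: DuplexFragment, cuts: list[tuple[int, Enzyme]], i: int) -> DuplexFragment:
    n = len(m.top)
    c0, e0 = cuts[i]
    c1, e1 = cuts[(i + 1) % len(cuts)]
    top = m.slice_top(c0, c1) if len(cuts) > 1 else m.top[c0:] + m.top[:c0]
    left = _sticky(e0, "top")
    right = _sticky(e1, "bottom")
    feats = []
    span = len(top)
    for f in m.features:
        s = (f.start - c0) % n
        e = s + (f.end - f.start)
        if e <= span:
            feats.append(_feat_copy(f, s, e))
    return DuplexFragment(top, LINEAR, left, right, feats, name=m.name)


def _linear_fragments(m: DuplexFragment, cuts: list[tuple[int, Enzyme]]) -> list[DuplexFragment]:
    frags = []
    bounds = [0] + [c for c, _ in cuts] + [len(m.top)]
    for i in range(len(bounds) - 1):
        a, b = bounds[i], bounds[i + 1]
        left = m.left_end if i == 0 else _sticky(cuts[i - 1][1], "top")
        right = m.right_end if i == len(bounds) - 2 else _sticky(cuts[i][1], "bottom")
        feats = [_feat_copy(f, f.start - a, f.end - a)
                 for f in m.features if a <= f.start and f.end <= b]
        frags.append(DuplexFragment(m.top[a:b], LINEAR, left, right, feats, name=m.name))
    return frags


def _feat_copy(f, s, e):
    from .seqcore import Feature

    return Feature(f.label, s, e, f.role, dict(f.meta))
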