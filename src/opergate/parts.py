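"""The operator-part standard: part design, validation, and insertion.

A *downstream* operator part is a short annealed duplex shaped so that it
can be ligated between the BglII and MluI sites of a platform plasmid's
downstream standard region, and so that the product can accept another part
by the same procedure:

* left end: 5' overhang ``GATC`` on the top strand (BamHI-made, and
  compatible with the backbone's BglII cut — isocaudamers);
* an operator sequence;
* one internal ``AGATCT`` (BglII) that becomes the region's new BglII site,
  because the ligation scar at the BamHI/BglII joint is cut by neither
  enzyme;
* a spacer, then a right end: 5' overhang ``CGCG`` on the bottom strand
  (MluI-made).

An *upstream* part (a promoter part) uses one of the sanctioned upstream
end pairs instead; see :func:`insert_upstream`.

Junction arithmetic worth knowing (it follows from the A^GATCT / A^CGCGT
cut geometry): the flanking ``A`` of both backbone sites leaves with the
discarded stuffer, so the product's MluI site is regenerated only when the
incoming top strand ends in ``A`` (the standard spacer does), and the
BamHI/BglII scar stays dead only when the operator does not begin with
``T``. :func:`design_downstream_part` enforces the forbidden-site rule the
standard states; the two junction rules are enforced by the part designs
shipped here and surfaced as findings by :func:`validate_downstream_part`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .assembly import insert_part
from .enzymes import find_sites, lookup
from .errors import DesignError, MetadataError, StandardViolationError
from .seqcore import (
    DuplexFragment,
    Feature,
    anneal_oligos,
    as_nuc,
    reverse_complement,
)

log = logging.getLogger(__name__)

REPRESSOR = "repressor"
ACTIVATOR = "activator"

#: Enzymes whose sites may not occur inside a downstream part payload.
DOWNSTREAM_FORBIDDEN = ("EcoRI", "XbaI", "SalI", "BamHI", "BglII", "MluI")

LEFT_OVERHANG = "GATC"  # BamHI-made, BglII-compatible
RIGHT_OVERHANG = "CGCG"  # MluI-made
BGLII_SITE = "AGATCT"
MLUI_SITE = "ACGCGT"


@dataclass(frozen=True)
class RegulatorSpec:
    """A transcription regulator archetype and its inducer.

    Exactly the two archetypes in scope are supported: an IPTG-style
    inducer that *releases a repressor* from its operator, and an AHL-style
    inducer that *enables an activator* to bind its operator. Other
    induction logics are rejected loudly rather than half-supported.
    """

    name: str
    mode: str
    inducer: str
    inducer_effect: str = ""

    def __post_init__(self) -> None:
        if self.mode not in (REPRESSOR, ACTIVATOR):
            raise MetadataError(f"unknown regulator mode {self.mode!r}")
        expected = "releases_repressor" if self.mode == REPRESSOR else "enables_activator"
        effect = self.inducer_effect or expected
        if effect != expected:
            raise MetadataError(
                f"{self.name}: mode {self.mode} requires inducer_effect {expected}, got {effect}"
            )
        object.__setattr__(self, "inducer_effect", effect)

    def as_meta(self) -> dict:
        return {
            "regulator_name": self.name,
            "regulator_mode": self.mode,
            "inducer": self.inducer,
            "inducer_effect": self.inducer_effect,
        }

    @classmethod
    def from_meta(cls, meta: dict) -> "RegulatorSpec":
        try:
            return cls(meta["regulator_name"], meta["regulator_mode"], meta["inducer"],
                       meta.get("inducer_effect", ""))
        except KeyError as exc:
            raise MetadataError(f"operator annotation missing regulator field {exc}") from exc


@dataclass
class OperatorPart:
    """A standardized insertable fragment plus its regulator metadata."""

    fragment: DuplexFragment
    regulator: RegulatorSpec | None
    operator_span: Feature | None = None
    spacer: str = ""
    part_class: str = "downstream"  # or "upstream"
    carries_promoter_core: bool = False
    carries_expression_cassette: bool = False
    name: str = ""


@dataclass
class PlatformReport:
    """Outcome of a conformance validation: named checks plus a verdict."""

    findings: list[tuple[str, bool, str]] = field(default_factory=list)
    advisory: list[tuple[str, bool, str]] = field(default_factory=list)

    def add(self, check: str, ok: bool, detail: str = "", *, mandatory: bool = True) -> None:
        (self.findings if mandatory else self.advisory).append((check, bool(ok), detail))

    @property
    def conforms(self) -> bool:
        return all(ok for _, ok, _ in self.findings)

    def failed(self) -> list[str]:
        return [c for c, ok, _ in self.findings if not ok]


# -- design -----------------------------------------------------------------


def design_downstream_part(
    operator_seq: str,
    spacer: str,
    regulator: RegulatorSpec,
    *,
    name: str = "",
) -> tuple[str, str, OperatorPart]:
    """Design the oligo pair for a downstream operator part.

    ``top = GATC + operator + AGATCT + spacer`` and
    ``bottom = CGCG + reverse_complement(operator + AGATCT + spacer)``;
    annealing the pair yields the standard part. The operator and spacer may
    not contain (or combine into) any recognition site of the six
    downstream-relevant enzymes beyond the single designed BglII site.
    """
    operator_seq = as_nuc(operator_seq, context="operator")
    spacer = as_nuc(spacer, context="spacer") if spacer else ""
    core = operator_seq + BGLII_SITE + spacer
    top = LEFT_OVERHANG + core
    bottom = RIGHT_OVERHANG + reverse_complement(core)
    for enz_name in DOWNSTREAM_FORBIDDEN:
        site = lookup(enz_name).recognition
        expected = 1 if site == BGLII_SITE else 0
        for payload, what in ((operator_seq, "operator"), (spacer, "spacer")):
            if site in payload:
                raise DesignError(f"{what} contains forbidden {enz_name} site {site}")
        if top.count(site) != expected:
            raise DesignError(
                f"assembled part carries a stray {enz_name} site {site} across a payload boundary"
            )
    fragment = anneal_oligos(top, bottom, name=name or "part")
    op_span = Feature(name or regulator.name + "-operator", len(LEFT_OVERHANG),
                      len(LEFT_OVERHANG) + len(operator_seq), "operator",
                      regulator.as_meta())
    fragment.features.append(op_span)
    part = OperatorPart(fragment, regulator, op_span, spacer, "downstream", name=name)
    return top, bottom, part


def validate_downstream_part(part: DuplexFragment | OperatorPart) -> PlatformReport:
    """Check a linear fragment against the downstream part standard.

    Mandatory checks: (1) left overhang GATC protruding on the top strand,
    (2) right overhang CGCG protruding on the bottom strand, (3) exactly one
    internal AGATCT, (4) no internal ACGCGT, (5) the operator annotation, if
    present, lies 5' of the BglII site. Two advisory findings report the
    junction rules (operator not starting with T; top strand ending in A)
    that keep the insertion scars correct.
    """
    frag = part.fragment if isinstance(part, OperatorPart) else part
    rep = PlatformReport()
    if frag.is_circular:
        rep.add("linear", False, "part must be a linear fragment")
        return rep
    le, ri = frag.left_end, frag.right_end
    rep.add("left_end_gatc", le.kind == "five_prime" and le.overhang == LEFT_OVERHANG
            and le.strand == "top",
            f"left end {le.kind}:{le.overhang or '-'} on {le.strand}")
    rep.add("right_end_cgcg", ri.kind == "five_prime" and ri.overhang == RIGHT_OVERHANG
            and ri.strand == "bottom",
            f"right end {ri.kind}:{ri.overhang or '-'} on {ri.strand}")
    n_bgl = frag.top.count(BGLII_SITE)
    rep.add("one_internal_bglii", n_bgl == 1, f"{n_bgl} AGATCT copies")
    n_mlu = frag.top.count(MLUI_SITE)
    rep.add("no_internal_mlui", n_mlu == 0, f"{n_mlu} ACGCGT copies")
    ops = frag.features_by_role("operator")
    if ops:
        bgl = frag.top.find(BGLII_SITE)
        rep.add("operator_before_bglii", bgl != -1 and all(o.end <= bgl for o in ops),
                f"operator ends {[o.end for o in ops]} vs BglII at {bgl}")
    core_start = len(le.overhang) if le.strand == "top" else 0
    rep.add("scar_safe_operator_start", frag.top[core_start : core_start + 1] != "T",
            "an operator starting with T would re-create AGATCT at the BamHI/BglII scar",
            mandatory=False)
    rep.add("mlui_regenerating_tail", frag.top.endswith("A"),
            "a top strand not ending in A does not regenerate the MluI site",
            mandatory=False)
    return rep


# -- platform validation ----------------------------------------------------

MCS_ENZYMES = ("EcoRI", "XbaI", "SalI", "BamHI")


def _sites_in(plasmid: DuplexFragment, enz_name: str, span: tuple[int, int]) -> list[int]:
    lo, hi = span
    rec_len = len(lookup(enz_name).recognition)
    out = []
    n = len(plasmid.top)
    for p in find_sites(plasmid, lookup(enz_name)).positions:
        end = p + rec_len
        if lo <= p and end <= hi:
            out.append(p)
        elif plasmid.is_circular and hi > n and lo <= p + n and p + n + rec_len <= hi:
            out.append(p)
    return out


def validate_platform(plasmid: DuplexFragment) -> PlatformReport:
    """Check a circular plasmid against the standardized platform layout.

    Mandatory always: exactly one BglII and one MluI inside the downstream
    standard region with BglII 5' of MluI; no BglII/MluI sites anywhere else
    on the plasmid; an rbs feature between the MluI site and the cds start.
    The upstream-MCS site checks (one each of EcoRI/XbaI/SalI/BamHI inside
    mcs_upstream) are mandatory on a virgin platform and advisory once a
    promoter part occupies the MCS, since installing a promoter part
    legitimately consumes its entry sites.
    """
    if not plasmid.is_circular:
        raise StandardViolationError("platform must be a circular plasmid")
    required = ("mcs_upstream", "downstream_region", "rbs", "cds")
    missing = [r for r in required if not plasmid.features_by_role(r)]
    if missing:
        raise MetadataError(f"platform missing required annotations: {missing}")
    rep = PlatformReport()
    mcs = plasmid.features_by_role("mcs_upstream")[0]
    down = plasmid.features_by_role("downstream_region")[0]
    rbs = plasmid.features_by_role("rbs")[0]
    cds = plasmid.features_by_role("cds")[0]
    virgin = not plasmid.features_by_role("promoter_core")

    for enz_name in MCS_ENZYMES:
        hits = _sites_in(plasmid, enz_name, (mcs.start, mcs.end))
        rep.add(f"mcs_{enz_name.lower()}_unique", len(hits) == 1,
                f"{len(hits)} {enz_name} sites in mcs_upstream", mandatory=virgin)

    bgl_in = _sites_in(plasmid, "BglII", (down.start, down.end))
    mlu_in = _sites_in(plasmid, "MluI", (down.start, down.end))
    rep.add("downstream_one_bglii", len(bgl_in) == 1, f"{len(bgl_in)} BglII sites in region")
    rep.add("downstream_one_mlui", len(mlu_in) == 1, f"{len(mlu_in)} MluI sites in region")
    rep.add("bglii_before_mlui",
            bool(bgl_in and mlu_in) and bgl_in[0] < mlu_in[0],
            f"BglII at {bgl_in}, MluI at {mlu_in}")
    for enz_name, inside in (("BglII", bgl_in), ("MluI", mlu_in)):
        total = find_sites(plasmid, lookup(enz_name)).positions
        stray = [p for p in total if p not in inside]
        rep.add(f"no_stray_{enz_name.lower()}", not stray,
                f"{enz_name} sites outside downstream region at {stray}")
    mlu_end = mlu_in[0] + 6 if mlu_in else down.end
    rep.add("rbs_between_mlui_and_cds", mlu_end <= rbs.start < rbs.end <= cds.start,
            f"rbs [{rbs.start},{rbs.end}) vs MluI end {mlu_end} and cds start {cds.start}")
    return rep


# -- standardized insertion entry points ------------------------------------


def insert_downstream(plasmid: DuplexFragment, part: OperatorPart) -> DuplexFragment:
    """Insert a downstream operator part between the platform's BglII and
    MluI sites.

    Both the platform and the part are validated first; the product passes
    platform validation again, with the new operator annotated downstream of
    all previously inserted operators and upstream of the RBS.
    """
    plat = validate_platform(plasmid)
    if not plat.conforms:
        raise StandardViolationError(f"platform does not conform: {plat.failed()}")
    prep = validate_downstream_part(part)
    if not prep.conforms:
        raise StandardViolationError(f"part does not conform: {prep.failed()}")
    product = insert_part(plasmid, part.fragment, (lookup("BglII"), lookup("MluI")))
    product.name = plasmid.name  # construct naming is the caller's business
    post = validate_platform(product)
    if not post.conforms:
        # reachable for junction-unsafe payloads (e.g. operator starting with T)
        raise StandardViolationError(f"product lost conformance: {post.failed()}")
    return product


UPSTREAM_PAIRS = {("SalI", "BglII"), ("EcoRI", "XbaI")}


def insert_upstream(
    plasmid: DuplexFragment,
    part: DuplexFragment | OperatorPart,
    pair: tuple[str, str],
) -> DuplexFragment:
    """Insert an upstream (promoter-bearing) part into the multi-cloning
    region using one of the sanctioned enzyme pairs.

    ``("EcoRI", "XbaI")`` accepts SpeI-ended parts: the XbaI/SpeI fusion
    scar is recuttable by neither enzyme. ``("SalI", "BglII")`` names the
    GATC-overhang chemistry of the part's right end; operationally the cut
    is made at SalI plus the GATC-class site (BamHI or BglII — isocaudamers
    with identical overhangs) that lies inside the upstream MCS, so that the
    downstream standard region's own BglII/MluI pair survives the insertion
    intact. On a platform whose MCS carries no GATC-class site the
    downstream BglII itself is used, which consumes it.
    """
    frag = part.fragment if isinstance(part, OperatorPart) else part
    key = tuple(pair)
    if key not in UPSTREAM_PAIRS:
        raise StandardViolationError(f"upstream pair {pair} not sanctioned; use {UPSTREAM_PAIRS}")
    plat = validate_platform(plasmid)
    if not plat.conforms:
        raise StandardViolationError(f"platform does not conform: {plat.failed()}")
    if key == ("EcoRI", "XbaI"):
        enzymes = (lookup("EcoRI"), lookup("XbaI"))
    else:
        mcs = plasmid.features_by_role("mcs_upstream")[0]
        gatc_class = None
        for cand in ("BamHI", "BglII"):
            if _sites_in(plasmid, cand, (mcs.start, mcs.end)):
                gatc_class = cand
                break
        if gatc_class is None:
            gatc_class = "BglII"
            log.warning("insert_upstream: no GATC-class site in the MCS; using the downstream "
                        "BglII site, which this insertion will consume")
        enzymes = (lookup("SalI"), lookup(gatc_class))
    product = insert_part(plasmid, frag, enzymes)
    product.name = plasmid.name
    return product
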