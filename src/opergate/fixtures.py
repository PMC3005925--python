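"""Canonical parts, the synthetic platform backbone, and pipeline fixtures.

The platform plasmid here is a *synthetic stand-in* for pSB-GFP: its
engineered regulatory region is fixed verbatim by the two mutagenesis
primer sequences (upstream multi-cloning region from the reverse complement
of the BamSal primer, downstream standard region + RBS + start codon from
the BglMlu primer), while the reporter coding sequence and the vector
filler (origin/marker territory, whose true sequence is unpublished) are
seeded pseudo-random DNA kept free of all seven recognition sites by
rejection sampling. Same seed, same backbone, byte for byte.

The LuxR cassette part is likewise a synthetic stand-in for the
EcoRI/SpeI fragment of a Registry part that is not printed anywhere: it
has the correct end chemistry (AATT / CTAG 5' overhangs), carries the real
20-bp lux box operator, and placeholder cassette and weak-promoter
segments.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import GenerationError, ParseError, StandardViolationError
from .logic import TruthTable, extract_model, truth_table
from .parts import (
    ACTIVATOR,
    REPRESSOR,
    OperatorPart,
    RegulatorSpec,
    design_downstream_part,
    insert_downstream,
    insert_upstream,
    validate_downstream_part,
    validate_platform,
)
from .seqcore import (
    CIRCULAR,
    DuplexFragment,
    Feature,
    anneal_oligos,
    reverse_complement,
)
from .enzymes import builtin_enzymes, find_sites

# -- printed sequences ------------------------------------------------------

#: Mutagenesis primers that defined the engineered regulatory region.
BGLMLU_RBS_PLUS = "GGAGATCTGTCGGATAACGCGTGAGATTAAAGAGGAGAAATACTAGATG"
BAMSAL_PSB3_MINUS = "GACAGGATCCAGTCGTCAGTCGACCTCTAGAAGCGGCCGCG"

#: Annealed oligo pairs for the two synthesized parts.
LACI_PART_TOP = "GATCGGAATTGTGAGCGGATAACAATTCCAGATCTATCGTAA"
LACI_PART_BOTTOM = "CGCGTTACGATAGATCTGGAATTGTTATCCGCTCACAATTCC"
LACI_OPERATOR = "GGAATTGTGAGCGGATAACAATTCC"
LACI_SPACER = "ATCGTAA"

PLACQ_TOP = "TCGACCGTGACGGATCCTGGTGCAAAACCTTTCGCGGTATGGCATGATAGCGCC"
PLACQ_BOTTOM = "GATCGGCGCTATCATGCCATACCGCGAAAGGTTTTGCACCAGGATCCGTCACGG"

#: The 20-bp lux box (LuxR operator) embedded in the synthetic cassette.
LUX_BOX = "ACCTGTAGGATCGTACAGGT"

#: Synthetic stand-in for the LuxR cassette EcoRI/SpeI fragment (top strand
#: including the AATT left overhang; the CTAG right overhang lives on the
#: bottom strand). Fixed literal, free of all seven recognition sites.
LUXR_SYNTHETIC_TOP = (
    "AATTCCGCGTCTCCCTGTACCCACGAGAGATGAGTGATCCCGGACATCAAGCCACGGACATGAGTAGTTGCC"
    "CCAGCCAATACGTTGCCGCGTGAAGGAGTAAACGTAGATTAGGAAATATCCCCAGGCAAGGTACCAAGGTAT"
    "TTTTCCGCGGCGTGTCAGGCATTGAAACTCGCTAATCGTGGTTAAACCTGTAGGATCGTACAGGTTTGACAC"
    "AAAGCTTGCCCTGTACTATAATGCTTAA"
)
_LUXR_CASSETTE_SPAN = (5, 179)
_LUXR_OPERATOR_SPAN = (189, 209)
_LUXR_CORE_SPAN = (209, 238)

LACI = RegulatorSpec("LacI", REPRESSOR, "IPTG")
LUXR = RegulatorSpec("LuxR", ACTIVATOR, "AHL")

#: Strains: regulators expressed from the host genome.
BUILTIN_STRAINS: dict[str, frozenset[str]] = {
    "DH5alpha": frozenset(),
    "DH5alphaLacI": frozenset({"LacI"}),
}

PLASMID_NAMES = (
    "pSB-GFP",
    "Placq-GFP",
    "Placq-LacI-GFP",
    "Placq-LacItandem-GFP",
    "PLuxR-GFP",
    "PLuxR-LacItandem-GFP",
)


# -- canonical parts --------------------------------------------------------


def lac_operator_part() -> OperatorPart:
    """The LacI operator part, rebuilt from its design formula.

    The designed oligos equal the synthesized pair byte for byte; the
    constructor asserts it so the fixture can never drift from the printed
    sequences.
    """
    top, bottom, part = design_downstream_part(
        LACI_OPERATOR, LACI_SPACER, LACI, name="lacO-part"
    )
    assert top == LACI_PART_TOP and bottom == LACI_PART_BOTTOM
    return part


def placq_part() -> OperatorPart:
    """The Placq constitutive promoter part (upstream class, TCGA/GATC ends)."""
    frag = anneal_oligos(PLACQ_TOP, PLACQ_BOTTOM, name="Placq")
    frag.features.append(
        Feature("placq", 4, len(PLACQ_TOP), "promoter_core",
                {"strength_class": "strong_constitutive"})
    )
    return OperatorPart(frag, None, None, "", "upstream",
                        carries_promoter_core=True, name="Placq")


def luxr_cassette_part() -> OperatorPart:
    """Synthetic LuxR cassette part: expression cassette + lux box + weak core."""
    bottom = "CTAG" + reverse_complement(LUXR_SYNTHETIC_TOP[4:])
    frag = anneal_oligos(LUXR_SYNTHETIC_TOP, bottom, name="PLuxR-cassette")
    frag.features.extend([
        Feature("luxR-cassette", *_LUXR_CASSETTE_SPAN, "expression_cassette",
                {"regulator_name": "LuxR"}),
        Feature("lux-box", *_LUXR_OPERATOR_SPAN, "operator", LUXR.as_meta()),
        Feature("luxpR", *_LUXR_CORE_SPAN, "promoter_core",
                {"strength_class": "weak_activator_dependent", **LUXR.as_meta()}),
    ])
    op = frag.features[1]
    return OperatorPart(frag, LUXR, op, "", "upstream",
                        carries_promoter_core=True, carries_expression_cassette=True,
                        name="PLuxR-cassette")


# -- synthetic backbone -----------------------------------------------------


@dataclass
class BackboneSpec:
    """Parameters of the synthetic platform backbone.

    ``downstream_sequence`` must embed exactly one AGATCT then one ACGCGT;
    ``rbs_to_cds`` must end in ATG. Defaults reproduce the engineered
    region verbatim from the printed primers.
    """

    mcs_sequence: str = "GAATTC" + reverse_complement(BAMSAL_PSB3_MINUS)
    downstream_sequence: str = BGLMLU_RBS_PLUS[:22]
    rbs_to_cds: str = BGLMLU_RBS_PLUS[22:]
    reporter_cds_length: int = 720
    filler_length: int = 1500
    seed: int = 0
    max_retries: int = 1000

    def __post_init__(self) -> None:
        d = self.downstream_sequence
        if d.count("AGATCT") != 1 or d.count("ACGCGT") != 1 or (
            d.find("AGATCT") > d.find("ACGCGT")
        ):
            raise ValueError("downstream_sequence must embed exactly one AGATCT then one ACGCGT")
        if not self.rbs_to_cds.endswith("ATG"):
            raise ValueError("rbs_to_cds must end at the reporter start codon ATG")
        if self.reporter_cds_length < 6 or self.filler_length < 0:
            raise ValueError("implausible reporter/filler lengths")


#: site counts a virgin platform must show (SpeI must be absent: it enters
#: only with upstream parts).
_EXPECTED_COUNTS = {
    "EcoRI": 1, "XbaI": 1, "SalI": 1, "BamHI": 1, "BglII": 1, "MluI": 1, "SpeI": 0,
}


def build_synthetic_backbone(spec: BackboneSpec | None = None) -> DuplexFragment:
    """Build the circular synthetic platform plasmid (pSB-GFP stand-in).

    Layout from the origin: EcoRI site, upstream MCS (NotI–XbaI–SalI–BamHI,
    the reverse complement of the BamSal primer), downstream standard
    region and RBS (the BglMlu primer verbatim), reporter CDS placeholder,
    then seeded-random filler. The random segments are rejection-sampled
    until the whole circle shows exactly the expected site counts; failure
    within the retry bound raises a generation error.
    """
    spec = spec or BackboneSpec()
    rng = random.Random(spec.seed)
    fixed = spec.mcs_sequence + spec.downstream_sequence + spec.rbs_to_cds
    cds_extra = spec.reporter_cds_length - 3  # ATG comes with rbs_to_cds
    for _attempt in range(spec.max_retries):
        cds_rest = "".join(rng.choice("ACGT") for _ in range(cds_extra - 3)) + "TAA"
        filler = "".join(rng.choice("ACGT") for _ in range(spec.filler_length))
        top = fixed + cds_rest + filler
        plasmid = DuplexFragment(top, CIRCULAR, None, None, name="pSB-GFP")
        counts = {e.name: len(find_sites(plasmid, e)) for e in builtin_enzymes()}
        if counts == _EXPECTED_COUNTS:
            break
    else:
        raise GenerationError(
            f"no site-free filler found in {spec.max_retries} attempts; "
            "shorten the random segments or change the seed"
        )
    mcs_end = len(spec.mcs_sequence)
    down_end = mcs_end + len(spec.downstream_sequence)
    cds_start = down_end + len(spec.rbs_to_cds) - 3
    plasmid.features.extend([
        Feature("upstream-MCS", 0, mcs_end, "mcs_upstream"),
        Feature("downstream-standard", mcs_end, down_end, "downstream_region"),
        Feature("rbs", down_end, cds_start, "rbs"),
        Feature("gfp", cds_start, cds_start + spec.reporter_cds_length, "cds"),
    ])
    report = validate_platform(plasmid)
    if not report.conforms:  # pragma: no cover - guarded by the count check
        raise GenerationError(f"generated backbone fails validation: {report.failed()}")
    return plasmid


# -- named constructs -------------------------------------------------------


def build_plasmid(name: str, seed: int = 0) -> DuplexFragment:
    """Construct any plasmid of the study by its published name.

    Each construct is produced by actually running the assembly operations
    (digest, ligate, insert) from the synthetic backbone, never by pasting
    a precomputed sequence.
    """
    backbone = build_synthetic_backbone(BackboneSpec(seed=seed))
    if name == "pSB-GFP":
        return backbone
    if name.startswith("Placq"):
        plasmid = insert_upstream(backbone, placq_part(), ("SalI", "BglII"))
    elif name.startswith("PLuxR"):
        plasmid = insert_upstream(backbone, luxr_cassette_part(), ("EcoRI", "XbaI"))
    else:
        raise KeyError(f"unknown plasmid name {name!r}; expected one of {PLASMID_NAMES}")
    plasmid.name = name.split("-")[0] + "-GFP"
    inserts = {"": 0, "LacI": 1, "LacItandem": 2}
    middle = name.split("-")[1] if name.count("-") == 2 else ""
    if middle not in inserts:
        raise KeyError(f"unknown plasmid name {name!r}; expected one of {PLASMID_NAMES}")
    for _ in range(inserts[middle]):
        plasmid = insert_downstream(plasmid, lac_operator_part())
    plasmid.name = name
    return plasmid


# -- randomized conforming parts --------------------------------------------


def random_downstream_part(
    rng: random.Random,
    *,
    operator_len: tuple[int, int] = (16, 30),
    spacer_len: tuple[int, int] = (4, 10),
    max_retries: int = 1000,
) -> OperatorPart:
    """A random operator part that conforms to the downstream standard.

    Payloads are resampled until the part passes validation *and* is
    junction-safe (operator not starting with T, spacer ending in A, and no
    stray site arising in the sealed insertion context), so that sequential
    insertion keeps the platform conformant — the property the standard is
    for.
    """
    for _ in range(max_retries):
        olen = rng.randint(*operator_len)
        slen = rng.randint(*spacer_len)
        operator = rng.choice("ACG") + "".join(rng.choice("ACGT") for _ in range(olen - 1))
        spacer = "".join(rng.choice("ACGT") for _ in range(slen - 1)) + "A"
        # sealed context after insertion: backbone contributes A...| and |CGCGT
        sealed = "A" + "GATC" + operator + "AGATCT" + spacer + "CGCGT"
        if any(sealed.count(e.recognition) != (1 if e.name in ("BglII", "MluI") else 0)
               for e in builtin_enzymes()):
            continue
        try:
            _, _, part = design_downstream_part(
                operator, spacer, LACI, name=f"random-op-{olen}x{slen}"
            )
        except Exception:  # noqa: BLE001 - resample on any design refusal
            continue
        if validate_downstream_part(part).conforms:
            return part
    raise GenerationError(f"no conforming random part found in {max_retries} attempts")


# -- part/strain files ------------------------------------------------------


def write_part_file(part: OperatorPart, path: str | Path) -> None:
    frag = part.fragment
    doc = {
        "name": part.name or frag.name,
        "class": part.part_class,
        "top_oligo": frag.top,
        "bottom_oligo": frag.bottom,
        "carries_expression_cassette": part.carries_expression_cassette,
    }
    if part.regulator is not None:
        doc["regulator"] = {
            "name": part.regulator.name,
            "mode": part.regulator.mode,
            "inducer": part.regulator.inducer,
        }
    if part.operator_span is not None:
        doc["operator_span"] = [part.operator_span.start, part.operator_span.end]
    extra = {}
    for f in frag.features:
        if f.role == "promoter_core":
            extra["promoter_core_span"] = [f.start, f.end]
            extra["promoter_strength"] = f.meta.get("strength_class")
        elif f.role == "expression_cassette":
            extra["cassette_span"] = [f.start, f.end]
    doc.update(extra)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_part_file(path: str | Path) -> OperatorPart:
    try:
        doc = yaml.safe_load(Path(path).read_text())
        name = doc["name"]
        part_class = doc["class"]
        frag = anneal_oligos(doc["top_oligo"], doc["bottom_oligo"], name=name)
    except (KeyError, TypeError, yaml.YAMLError) as exc:
        raise ParseError(f"malformed part file {path}: {exc}") from exc
    regulator = None
    if "regulator" in doc:
        r = doc["regulator"]
        regulator = RegulatorSpec(r["name"], r["mode"], r["inducer"])
    op_feat = None
    if "operator_span" in doc and regulator is not None:
        s, e = doc["operator_span"]
        op_feat = Feature(f"{regulator.name}-operator", s, e, "operator", regulator.as_meta())
        frag.features.append(op_feat)
    if "promoter_core_span" in doc:
        s, e = doc["promoter_core_span"]
        meta = {"strength_class": doc.get("promoter_strength", "strong_constitutive")}
        if meta["strength_class"] == "weak_activator_dependent" and regulator is not None:
            meta.update(regulator.as_meta())
        frag.features.append(Feature(f"{name}-core", s, e, "promoter_core", meta))
    if "cassette_span" in doc and regulator is not None:
        s, e = doc["cassette_span"]
        frag.features.append(Feature(f"{name}-cassette", s, e, "expression_cassette",
                                     {"regulator_name": regulator.name}))
    return OperatorPart(
        frag, regulator, op_feat, "", part_class,
        carries_promoter_core="promoter_core_span" in doc,
        carries_expression_cassette=bool(doc.get("carries_expression_cassette")),
        name=name,
    )


def load_strains(path: str | Path | None = None) -> dict[str, frozenset[str]]:
    """Strain → expressed-regulator sets; built-ins unless a YAML file is given."""
    if path is None:
        return dict(BUILTIN_STRAINS)
    try:
        doc = yaml.safe_load(Path(path).read_text())
        return {name: frozenset(regs or []) for name, regs in doc["strains"].items()}
    except (KeyError, TypeError, yaml.YAMLError) as exc:
        raise ParseError(f"malformed strain file {path}: {exc}") from exc


# -- full pipeline ----------------------------------------------------------


def make_and_gate(strain: str = "DH5alphaLacI", seed: int = 0,
                  strains: dict[str, frozenset[str]] | None = None
                  ) -> tuple[DuplexFragment, TruthTable]:
    """Run the whole construction pipeline to the two-input gate.

    Build the synthetic backbone, install the LuxR cassette upstream,
    insert the LacI operator part twice downstream, validate the platform
    at every stage, then derive the truth table in the given strain.
    """
    strains = strains or load_strains()
    if strain not in strains:
        raise KeyError(f"unknown strain {strain!r}; known: {sorted(strains)}")
    plasmid = build_plasmid("PLuxR-LacItandem-GFP", seed=seed)
    report = validate_platform(plasmid)
    if not report.conforms:  # pragma: no cover - insert_downstream re-validates
        raise StandardViolationError(f"final construct fails validation: {report.failed()}")
    model = extract_model(plasmid, strains[strain])
    return plasmid, truth_table(model)
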