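"""Part design/validation and the standardized insertion entry points."""

import pytest

from opergate import (
    DuplexFragment,
    anneal_oligos,
    design_downstream_part,
    find_sites,
    insert_downstream,
    insert_upstream,
    lookup,
    random_downstream_part,
    validate_downstream_part,
    validate_platform,
)
from opergate.errors import DesignError, MetadataError, StandardViolationError
from opergate.fixtures import (
    LACI,
    LACI_OPERATOR,
    LACI_PART_BOTTOM,
    LACI_PART_TOP,
    LACI_SPACER,
)
from opergate.parts import RegulatorSpec
from opergate.seqcore import CIRCULAR, Feature, reverse_complement


def test_design_reproduces_the_synthesized_laco_oligos():
    top, bottom, part = design_downstream_part(LACI_OPERATOR, LACI_SPACER, LACI)
    assert top == LACI_PART_TOP
    assert bottom == LACI_PART_BOTTOM
    assert validate_downstream_part(part).conforms


def test_design_formula_for_an_arbitrary_payload():
    top, bottom, _ = design_downstream_part("AAAATTTT", "", LACI)
    assert top == "GATC" + "AAAATTTT" + "AGATCT"
    assert bottom == "CGCG" + reverse_complement("AAAATTTT" + "AGATCT")


@pytest.mark.parametrize(
    ("operator", "spacer", "match"),
    [
        ("AAACGCGTAA", "ATCGTAA", "MluI"),  # forbidden site in operator
        ("GGAATTGTGA", "GGATCCA", "BamHI"),  # forbidden site in spacer
        ("GGAATTGTGA", "CTAGAA", "XbaI"),  # TCTAGA formed across the BglII/spacer boundary
    ],
)
def test_design_rejects_forbidden_sites(operator, spacer, match):
    with pytest.raises(DesignError, match=match):
        design_downstream_part(operator, spacer, LACI)


def test_validate_part_rejects_swapped_overhangs(lac_part):
    report = validate_downstream_part(lac_part.fragment.flipped())
    assert not report.conforms
    assert {"left_end_gatc", "right_end_cgcg"} <= set(report.failed())


def _downstream_shaped(core):
    from opergate.seqcore import StickyEnd

    return DuplexFragment(
        "GATC" + core,
        left_end=StickyEnd("five_prime", "GATC", "top"),
        right_end=StickyEnd("five_prime", "CGCG", "bottom"),
    )


def test_validate_part_counts_internal_sites():
    two_bgl = _downstream_shaped("AAGATCTAAA" + "AGATCT" + "AA")
    assert "one_internal_bglii" in validate_downstream_part(two_bgl).failed()
    with_mlu = _downstream_shaped("AAACGCGTAA" + "AGATCT" + "AA")
    assert "no_internal_mlui" in validate_downstream_part(with_mlu).failed()


def test_validate_part_checks_operator_position(lac_part):
    frag = lac_part.fragment
    late_op = DuplexFragment(frag.top, left_end=frag.left_end, right_end=frag.right_end)
    late_op.features.append(Feature("late", 36, 40, "operator", LACI.as_meta()))
    assert "operator_before_bglii" in validate_downstream_part(late_op).failed()


def test_regulator_archetypes_are_enforced():
    with pytest.raises(MetadataError):
        RegulatorSpec("TetR", "corepressor", "aTc")
    with pytest.raises(MetadataError):
        RegulatorSpec("LacI", "repressor", "IPTG", "enables_activator")


# -- platform validation ----------------------------------------------------


def test_platform_validation_passes_the_synthetic_backbone(backbone):
    report = validate_platform(backbone)
    assert report.conforms
    assert not report.failed()


def test_platform_validation_fails_without_mlui(backbone):
    mutated = DuplexFragment(
        backbone.top.replace("ACGCGT", "ACGCGA"), CIRCULAR, None, None,
        [f.shifted(0) for f in backbone.features],
    )
    report = validate_platform(mutated)
    assert not report.conforms
    assert "downstream_one_mlui" in report.failed()


def test_platform_validation_flags_stray_downstream_sites(backbone):
    stray = DuplexFragment(
        backbone.top + "TTACGCGTTT", CIRCULAR, None, None,
        [f.shifted(0) for f in backbone.features],
    )
    assert "no_stray_mlui" in validate_platform(stray).failed()


def test_platform_validation_requires_annotations(backbone):
    bare = DuplexFragment(backbone.top, CIRCULAR, None, None)
    with pytest.raises(MetadataError):
        validate_platform(bare)


def test_post_insertion_platform_keeps_conforming(constructs):
    for name in ("Placq-GFP", "Placq-LacI-GFP", "Placq-LacItandem-GFP",
                 "PLuxR-GFP", "PLuxR-LacItandem-GFP"):
        assert validate_platform(constructs[name]).conforms, name


# -- insertion entry points -------------------------------------------------


def test_insert_downstream_places_each_operator_after_its_predecessors(backbone, lac_part, rng):
    plasmid = backbone
    starts = []
    for _ in range(4):
        plasmid = insert_downstream(plasmid, random_downstream_part(rng))
        starts = [f.start for f in plasmid.features_by_role("operator")]
        assert starts == sorted(starts)
    rbs = plasmid.features_by_role("rbs")[0]
    assert all(s < rbs.start for s in starts)
    assert len(starts) == 4


def test_insert_downstream_rejects_nonconforming_part(backbone):
    bad = anneal_oligos(
        "GATC" + "AAACGCGTAA" + "AGATCT" + "AA",
        "CGCG" + reverse_complement("AAACGCGTAA" + "AGATCT" + "AA"),
    )
    from opergate.parts import OperatorPart

    with pytest.raises(StandardViolationError):
        insert_downstream(backbone, OperatorPart(bad, LACI))


def test_insert_upstream_placq_preserves_the_downstream_region(backbone, placq):
    product = insert_upstream(backbone, placq, ("SalI", "BglII"))
    down = product.features_by_role("downstream_region")[0]
    region = product.top[down.start : down.end]
    assert region == "GGAGATCTGTCGGATAACGCGT"  # untouched, primer-verbatim
    assert validate_platform(product).conforms
    # the SalI scar is regenerated, the MCS BamHI entry consumed and replaced
    # by the part's internal BamHI
    assert len(find_sites(product, lookup("SalI"))) == 1
    assert len(find_sites(product, lookup("BamHI"))) == 1


def test_insert_upstream_luxr_via_ecorixbai(backbone, luxr):
    product = insert_upstream(backbone, luxr, ("EcoRI", "XbaI"))
    assert validate_platform(product).conforms
    # EcoRI regenerated at the left scar; XbaI/SpeI fusion scar dead
    assert len(find_sites(product, lookup("EcoRI"))) == 1
    assert len(find_sites(product, lookup("XbaI"))) == 0
    assert len(find_sites(product, lookup("SpeI"))) == 0


def test_insert_upstream_rejects_wrong_pair(backbone, placq):
    with pytest.raises(Exception):
        insert_upstream(backbone, placq, ("EcoRI", "XbaI"))  # TCGA/GATC vs AATT/CTAG
    with pytest.raises(StandardViolationError):
        insert_upstream(backbone, placq, ("SalI", "MluI"))  # unsanctioned pair


def test_design_anneal_validate_roundtrip_on_random_payloads(rng):
    for _ in range(50):
        part = random_downstream_part(rng)
        report = validate_downstream_part(part)
        assert report.conforms
        assert all(ok for _, ok, _ in report.advisory)
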