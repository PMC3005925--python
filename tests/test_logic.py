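"""Boolean promoter logic: model extraction, evaluation, gate taxonomy."""

import random

import pytest

from opergate import InputState, classify_gate, evaluate, extract_model, truth_table
from opergate.errors import GateSizeError, MetadataError
from opergate.logic import (
    ABSENT,
    AND,
    BUFFER,
    CONSTITUTIVE,
    NOT,
    NULL,
    OFF,
    ON,
    OR,
    OTHER,
    STRONG,
    WEAK,
    PromoterCore,
    RegulatoryModel,
    TruthTable,
)
from opergate.parts import RegulatorSpec

LACI = RegulatorSpec("LacI", "repressor", "IPTG")
LUXR = RegulatorSpec("LuxR", "activator", "AHL")


# -- model extraction -------------------------------------------------------


def test_extract_model_from_the_two_input_construct(constructs):
    model = extract_model(constructs["PLuxR-LacItandem-GFP"], {"LacI"})
    assert model.promoter.strength_class == WEAK
    assert model.promoter.linked_activator.name == "LuxR"
    kinds = [(spec.name, pos) for spec, pos in model.operators]
    assert kinds == [
        ("LuxR", "upstream_of_core"),
        ("LacI", "downstream_of_core"),
        ("LacI", "downstream_of_core"),
    ]
    assert model.strain_regulators == {"LacI", "LuxR"}  # cassette adds LuxR


def test_extract_model_promoterless_and_constitutive(constructs):
    assert extract_model(constructs["pSB-GFP"], {"LacI"}).promoter.strength_class == ABSENT
    model = extract_model(constructs["Placq-GFP"], set())
    assert model.promoter.strength_class == STRONG
    assert model.operators == []


def test_extract_model_requires_regulator_metadata(backbone):
    from opergate.seqcore import Feature

    broken = backbone.rotated(0)
    broken.features.append(Feature("orphan-op", 10, 20, "operator"))
    with pytest.raises(MetadataError):
        extract_model(broken, set())


# -- evaluation -------------------------------------------------------------


def laci_tandem_model():
    return RegulatoryModel(
        PromoterCore("placq", STRONG),
        [(LACI, "downstream_of_core"), (LACI, "downstream_of_core")],
        frozenset({"LacI"}),
    )


def pluxr_model(with_lac=False):
    ops = [(LUXR, "upstream_of_core")]
    if with_lac:
        ops += [(LACI, "downstream_of_core")] * 2
    return RegulatoryModel(PromoterCore("luxpR", WEAK, LUXR), ops, frozenset({"LacI", "LuxR"}))


@pytest.mark.parametrize(
    ("model_fn", "present", "expected"),
    [
        (laci_tandem_model, ("IPTG",), ON),
        (laci_tandem_model, (), OFF),
        (lambda: pluxr_model(False), ("AHL",), ON),
        (lambda: pluxr_model(False), (), OFF),
        (lambda: pluxr_model(True), (), OFF),
        (lambda: pluxr_model(True), ("IPTG",), OFF),
        (lambda: pluxr_model(True), ("AHL",), OFF),
        (lambda: pluxr_model(True), ("IPTG", "AHL"), ON),
    ],
)
def test_evaluate_reproduces_the_reporter_outcomes(model_fn, present, expected):
    assert evaluate(model_fn(), InputState.of(*present)) == expected


def test_unavailable_repressor_never_represses():
    model = laci_tandem_model()
    model.strain_regulators = frozenset()  # plain DH5alpha: no LacI anywhere
    assert evaluate(model, InputState.of()) == ON


def test_weak_promoter_without_activator_is_null():
    model = pluxr_model(False)
    model.strain_regulators = frozenset({"LacI"})  # LuxR absent
    assert truth_table(model).gate_label == NULL


# -- truth tables and classification ----------------------------------------

EXPECTED_GATES = {
    "pSB-GFP": NULL,
    "Placq-GFP": CONSTITUTIVE,
    "Placq-LacI-GFP": BUFFER,
    "Placq-LacItandem-GFP": BUFFER,
    "PLuxR-GFP": BUFFER,
    "PLuxR-LacItandem-GFP": AND,
}


def test_truth_tables_of_all_constructs(constructs):
    for name, expected in EXPECTED_GATES.items():
        model = extract_model(constructs[name], {"LacI"})
        table = truth_table(model)
        assert table.gate_label == expected, name


def test_and_gate_is_on_in_exactly_one_of_four_rows(constructs):
    table = truth_table(extract_model(constructs["PLuxR-LacItandem-GFP"], {"LacI"}))
    assert len(table.rows) == 4
    assert table.on_rows() == 1
    assert table.rows[frozenset({"IPTG", "AHL"})] == ON


def _table(inputs, on_sets):
    rows = {}
    for r in range(2 ** len(inputs)):
        combo = frozenset(x for i, x in enumerate(inputs) if r >> i & 1)
        rows[combo] = ON if combo in on_sets else OFF
    return TruthTable(list(inputs), rows)


def test_classify_gate_taxonomy():
    a, b, c = "x", "y", "z"
    assert classify_gate(_table([a], set())) == NULL
    assert classify_gate(_table([a], {frozenset(), frozenset({a})})) == CONSTITUTIVE
    assert classify_gate(_table([a], {frozenset({a})})) == BUFFER
    assert classify_gate(_table([a], {frozenset()})) == NOT
    both = frozenset({a, b})
    assert classify_gate(_table([a, b], {both})) == AND
    assert classify_gate(_table([a, b], {both, frozenset({a}), frozenset({b})})) == OR
    assert classify_gate(_table([a, b], {frozenset({a})})) == OTHER
    allthree = frozenset({a, b, c})
    assert classify_gate(_table([a, b, c], {allthree})) == AND
    nonempty = {frozenset(s) for s in
                [{a}, {b}, {c}, {a, b}, {a, c}, {b, c}, {a, b, c}]}
    assert classify_gate(_table([a, b, c], nonempty)) == OR


def test_classify_rejects_incomplete_tables():
    t = _table(["x", "y"], set())
    del t.rows[frozenset({"x"})]
    with pytest.raises(ValueError):
        classify_gate(t)


def test_truth_table_guards_input_explosion():
    ops = [(RegulatorSpec(f"R{i}", "repressor", f"ind{i}"), "downstream_of_core")
           for i in range(9)]
    model = RegulatoryModel(PromoterCore("p", STRONG), ops,
                            frozenset(f"R{i}" for i in range(9)))
    with pytest.raises(GateSizeError):
        truth_table(model)


def test_classification_is_invariant_under_input_reordering(constructs):
    model = extract_model(constructs["PLuxR-LacItandem-GFP"], {"LacI"})
    table = truth_table(model)
    reordered = TruthTable(list(reversed(table.inputs)), dict(table.rows))
    assert classify_gate(reordered) == table.gate_label


# -- invariants over random models ------------------------------------------


def random_model(rng):
    regs = [RegulatorSpec(f"R{i}", rng.choice(["repressor", "activator"]), f"I{i}")
            for i in range(rng.randint(0, 4))]
    activators = [r for r in regs if r.mode == "activator"]
    strength = rng.choice([STRONG, WEAK, ABSENT])
    if strength == WEAK and not activators:
        strength = STRONG
    core = PromoterCore("p", strength,
                        rng.choice(activators) if strength == WEAK else None)
    ops = [(r, rng.choice(["upstream_of_core", "downstream_of_core"])) for r in regs]
    available = frozenset(r.name for r in regs if rng.random() < 0.8)
    return RegulatoryModel(core, ops, available)


def test_adding_an_inducer_never_switches_output_off():
    """Both induction archetypes are activating, so output is monotone in
    the inducer set."""
    rng = random.Random(11)
    for _ in range(300):
        model = random_model(rng)
        inducers = model.inducers
        state = frozenset(i for i in inducers if rng.random() < 0.5)
        extra = [i for i in inducers if i not in state]
        if not extra:
            continue
        before = evaluate(model, InputState(state))
        after = evaluate(model, InputState(state | {rng.choice(extra)}))
        assert not (before == ON and after == OFF)


def test_adding_a_repressor_operator_shrinks_the_on_set():
    rng = random.Random(12)
    for _ in range(200):
        model = random_model(rng)
        if len(model.inducers) >= 8:
            continue
        extra = RegulatorSpec("Rx", "repressor", "Ix")
        bigger = RegulatoryModel(
            model.promoter,
            model.operators + [(extra, "downstream_of_core")],
            model.strain_regulators | {"Rx"},
        )
        base = truth_table(model)
        widened = truth_table(bigger)
        for combo, value in base.rows.items():
            assert not (widened.rows[combo] == ON and value == OFF)
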