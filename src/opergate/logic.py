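"""Boolean transcription logic of an assembled regulatory region.

The model is deliberately Boolean, not graded: transcription is ON or OFF
for a given set of inducers. RNA polymerase fires a strong constitutive
-35/-10 core unconditionally, and a weak activator-dependent core (like
luxpR) only when its linked activator protein is available *and* its
inducer is present. Any repressor-mode operator whose regulator is
available and whose inducer is absent silences the unit. Operator position
(upstream/downstream of the core) is recorded but does not change the
Boolean semantics, and multiple copies of the same operator are logically
idempotent — copy number matters for expression strength, which this layer
does not model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

from .errors import GateSizeError, MetadataError
from .parts import ACTIVATOR, REPRESSOR, RegulatorSpec
from .seqcore import DuplexFragment

STRONG = "strong_constitutive"
WEAK = "weak_activator_dependent"
ABSENT = "absent"

ON = "ON"
OFF = "OFF"

NULL = "NULL"
CONSTITUTIVE = "CONSTITUTIVE"
BUFFER = "BUFFER"
NOT = "NOT"
AND = "AND"
OR = "OR"
OTHER = "OTHER"

MAX_INPUTS = 8


@dataclass(frozen=True)
class PromoterCore:
    """A -35/-10 element and its strength class."""

    label: str
    strength_class: str
    linked_activator: RegulatorSpec | None = None

    def __post_init__(self) -> None:
        if self.strength_class not in (STRONG, WEAK, ABSENT):
            raise MetadataError(f"unknown promoter strength class {self.strength_class!r}")
        if self.strength_class == WEAK and self.linked_activator is None:
            raise MetadataError(f"{self.label}: weak core requires a linked activator")
        if self.linked_activator is not None and self.linked_activator.mode != ACTIVATOR:
            raise MetadataError(f"{self.label}: linked regulator must be an activator")


PROMOTERLESS = PromoterCore("promoterless", ABSENT)


@dataclass
class RegulatoryModel:
    """Ordered promoter/operator elements plus available regulators."""

    promoter: PromoterCore
    operators: list[tuple[RegulatorSpec, str]] = field(default_factory=list)  # (spec, position)
    strain_regulators: frozenset[str] = frozenset()

    @property
    def inducers(self) -> list[str]:
        """All inducers the model's elements respond to, 5'→3' then promoter."""
        seen: dict[str, None] = {}
        for spec, _pos in self.operators:
            seen.setdefault(spec.inducer)
        if self.promoter.linked_activator is not None:
            seen.setdefault(self.promoter.linked_activator.inducer)
        return list(seen)


@dataclass(frozen=True)
class InputState:
    """The set of inducer molecules present in the environment."""

    present_inducers: frozenset[str] = frozenset()

    @classmethod
    def of(cls, *names: str) -> "InputState":
        return cls(frozenset(names))


@dataclass
class TruthTable:
    """Output for every combination of the model's inducer inputs."""

    inputs: list[str]
    rows: dict[frozenset[str], str]
    gate_label: str = ""

    def row_key(self, combo: frozenset[str]) -> str:
        present = [i for i in self.inputs if i in combo]
        return "+".join(present) if present else "none"

    def as_dict(self) -> dict:
        return {
            "inputs": list(self.inputs),
            "rows": {self.row_key(c): v for c, v in sorted(
                self.rows.items(), key=lambda kv: (len(kv[0]), self.row_key(kv[0])))},
            "gate": self.gate_label,
        }

    def on_rows(self) -> int:
        return sum(1 for v in self.rows.values() if v == ON)


# -- operations -------------------------------------------------------------


def extract_model(plasmid: DuplexFragment, strain_regulators: set[str] | frozenset[str]
                  ) -> RegulatoryModel:
    """Read the regulatory model off a plasmid's annotations.

    Operators are ordered 5'→3'; the promoter class comes from the
    promoter_core annotation (a plasmid without one is promoterless);
    regulators expressed by plasmid-borne cassettes are added to the
    strain's regulator set — availability is one pool regardless of whether
    the gene sits on the host genome or the plasmid.
    """
    promoter = PROMOTERLESS
    cores = plasmid.features_by_role("promoter_core")
    if len(cores) > 1:
        raise MetadataError("more than one promoter_core annotation")
    if cores:
        core = cores[0]
        strength = core.meta.get("strength_class")
        if strength is None:
            raise MetadataError(f"promoter_core {core.label!r} lacks strength_class metadata")
        linked = None
        if "regulator_name" in core.meta:
            linked = RegulatorSpec.from_meta(core.meta)
        promoter = PromoterCore(core.label, strength, linked)
    operators: list[tuple[RegulatorSpec, str]] = []
    for feat in plasmid.features_by_role("operator"):
        spec = RegulatorSpec.from_meta(feat.meta)
        position = "downstream_of_core"
        if cores and feat.end <= cores[0].start:
            position = "upstream_of_core"
        operators.append((spec, position))
    available = set(strain_regulators)
    for cassette in plasmid.features_by_role("expression_cassette"):
        name = cassette.meta.get("regulator_name")
        if name:
            available.add(name)
    return RegulatoryModel(promoter, operators, frozenset(available))


def evaluate(model: RegulatoryModel, state: InputState) -> str:
    """ON or OFF for one environment."""
    if model.promoter.strength_class == ABSENT:
        return OFF
    if model.promoter.strength_class == STRONG:
        polymerase_ok = True
    else:
        act = model.promoter.linked_activator
        polymerase_ok = (act.name in model.strain_regulators
                         and act.inducer in state.present_inducers)
    repressed = any(
        spec.mode == REPRESSOR
        and spec.name in model.strain_regulators
        and spec.inducer not in state.present_inducers
        for spec, _pos in model.operators
    )
    return ON if polymerase_ok and not repressed else OFF


def truth_table(model: RegulatoryModel) -> TruthTable:
    """Evaluate the model over all 2^n inducer combinations and classify."""
    inducers = model.inducers
    if len(inducers) > MAX_INPUTS:
        raise GateSizeError(f"{len(inducers)} inputs exceed the {MAX_INPUTS}-input guard")
    rows: dict[frozenset[str], str] = {}
    for r in range(len(inducers) + 1):
        for combo in combinations(inducers, r):
            key = frozenset(combo)
            rows[key] = evaluate(model, InputState(key))
    table = TruthTable(inducers, rows)
    table.gate_label = classify_gate(table)
    return table


def classify_gate(table: TruthTable) -> str:
    """Name the Boolean function a complete truth table implements."""
    n = len(table.inputs)
    expected_rows = 2 ** n
    if len(table.rows) != expected_rows:
        raise ValueError(f"incomplete table: {len(table.rows)} rows for {n} inputs")
    values = table.rows
    all_inputs = frozenset(table.inputs)
    if all(v == OFF for v in values.values()):
        return NULL
    if all(v == ON for v in values.values()):
        return CONSTITUTIVE
    if n == 1:
        return BUFFER if values[all_inputs] == ON else NOT
    is_and = all((v == ON) == (k == all_inputs) for k, v in values.items())
    if is_and:
        return AND
    is_or = all((v == ON) == bool(k) for k, v in values.items())
    if is_or:
        return OR
    return OTHER
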