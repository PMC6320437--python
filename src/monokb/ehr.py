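"""Match EHR-style patient records against defined patient groups and
retrieve customized, deduplicated facts.

A patient record is rendered as a class expression (realization): the patient
anchor plus existential restrictions for sex, ethnicity, every age group whose
interval or threshold contains the age, and every parsed variant. A defined
group matches when the record expression is structurally subsumed by the
group's definition. Absent attributes simply contribute no conjuncts — a group
requiring ``sex some female`` never matches a record without a sex code (open
world, no negation-as-failure).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

from .kb import (
    ClassExpression,
    ConceptId,
    Conjunction,
    Existential,
    KnowledgeBase,
    Named,
    normalize,
)
from .nomenclature import parse_label
from .reasoner import _Subsumer, Taxonomy, classify

log = logging.getLogger(__name__)

DEFAULT_SECTION = "general"


@dataclass(frozen=True)
class PatientRecord:
    age_years: float
    sex: Optional[str] = None
    ethnicity: Optional[str] = None
    diagnoses: tuple[str, ...] = ()
    variants: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.age_years < 0:
            raise ValueError("age_years must be non-negative")
        for label in self.variants:
            parse_label(label)  # propagate parse errors naming the label

    @classmethod
    def from_json(cls, text: str) -> "PatientRecord":
        d = json.loads(text)
        return cls(
            age_years=d["age_years"],
            sex=d.get("sex"),
            ethnicity=d.get("ethnicity"),
            diagnoses=tuple(d.get("diagnoses", ())),
            variants=tuple(d.get("variants", ())),
        )


@dataclass
class AgeGroupTable:
    """Interval groups partition [0, inf); threshold groups (min-age only,
    e.g. "at least 6 years") may overlap them."""

    intervals: list[tuple[str, float, Optional[float]]]  # (name, min, max-excl)
    thresholds: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ivs = sorted(self.intervals, key=lambda t: t[1])
        edge = 0.0
        for name, lo, hi in ivs:
            if lo != edge:
                raise ValueError(
                    f"age intervals must tile [0, inf): gap/overlap at {lo} ({name})"
                )
            if hi is not None and hi <= lo:
                raise ValueError(f"empty age interval {name}")
            edge = hi if hi is not None else float("inf")
        if edge != float("inf"):
            raise ValueError("age intervals must cover all ages (last max = null)")

    def groups_for(self, age: float) -> list[str]:
        out = [
            name
            for name, lo, hi in self.intervals
            if age >= lo and (hi is None or age < hi)
        ]
        out += [name for name, lo in self.thresholds if age >= lo]
        return out


DEFAULT_AGE_TABLE = AgeGroupTable(
    intervals=[
        ("infant", 0, 1),
        ("child", 1, 13),
        ("adolescent", 13, 18),
        ("adult", 18, None),
    ],
    thresholds=[("age_6_or_older", 6)],
)


@dataclass
class EhrConfig:
    """Property vocabulary plus the flat property -> EHR-section mapping."""

    anchor_class: str = "Patient"
    diagnosis_property: str = "has_diagnosis"
    sex_property: str = "sex"
    ethnicity_property: str = "ethnic_group"
    age_property: str = "age_group"
    mutation_property: str = "has_mutation"
    age_table: AgeGroupTable = field(default_factory=lambda: DEFAULT_AGE_TABLE)
    sections: dict[str, str] = field(default_factory=dict)


DEFAULT_CONFIG = EhrConfig()


@dataclass
class FactBundle:
    """Deduplicated facts, ordered most-specific source first."""

    entries: list[tuple[str, str, ClassExpression, str]] = field(
        default_factory=list
    )  # (source_group, property, filler, ehr_section)

    def __len__(self) -> int:
        return len(self.entries)

    def as_dict(self) -> list[dict]:
        return [
            {
                "source_group": g,
                "property": p,
                "filler": str(f),
                "ehr_section": s,
            }
            for g, p, f, s in self.entries
        ]


def patient_to_expression(
    patient: PatientRecord,
    table: Optional[AgeGroupTable] = None,
    config: EhrConfig = DEFAULT_CONFIG,
) -> Optional[ClassExpression]:
    """Realize a record as a class expression; None if the record is empty."""
    table = table or config.age_table
    ops: list[ClassExpression] = []
    if patient.diagnoses:
        ops.append(Named(ConceptId(config.anchor_class)))
        for d in patient.diagnoses:
            ops.append(
                Existential(ConceptId(config.diagnosis_property), Named(ConceptId(d)))
            )
    if patient.sex:
        ops.append(
            Existential(ConceptId(config.sex_property), Named(ConceptId(patient.sex)))
        )
    if patient.ethnicity:
        ops.append(
            Existential(
                ConceptId(config.ethnicity_property),
                Named(ConceptId(patient.ethnicity)),
            )
        )
    for group in table.groups_for(patient.age_years):
        ops.append(
            Existential(ConceptId(config.age_property), Named(ConceptId(group)))
        )
    for label in patient.variants:
        parse_label(label)
        ops.append(
            Existential(ConceptId(config.mutation_property), Named(ConceptId(label)))
        )
    if not ops:
        return None
    return normalize(Conjunction(tuple(ops))) if len(ops) > 1 else ops[0]


def match_patient_groups(
    kb: KnowledgeBase,
    patient: PatientRecord,
    table: Optional[AgeGroupTable] = None,
    config: EhrConfig = DEFAULT_CONFIG,
) -> list[str]:
    """All defined complex concepts the record realizes, most specific first
    (a matched group precedes every matched group that subsumes it; ties are
    broken lexicographically)."""
    expr = patient_to_expression(patient, table, config)
    if expr is None:
        return []
    s = _Subsumer(kb)
    matched = []
    for name, info in sorted(kb.concepts.items()):
        if info.level != "complex":
            continue
        definition = kb.definition_of(name)
        if definition is None:
            continue
        if s.subsumes(expr, definition):
            matched.append(name)
    # specificity (topological) order
    strict = {
        a: {
            b
            for b in matched
            if a != b
            and s.subsumes(Named(ConceptId(a)), Named(ConceptId(b)))
            and not s.subsumes(Named(ConceptId(b)), Named(ConceptId(a)))
        }
        for a in matched
    }
    ordered: list[str] = []
    remaining = set(matched)
    while remaining:
        ready = sorted(
            a
            for a in remaining
            if not any(a in strict[b] for b in remaining if b != a)
        )
        if not ready:  # equivalence cluster: emit lexicographically
            ready = sorted(remaining)
        ordered.append(ready[0])
        remaining.discard(ready[0])
    return ordered


def retrieve_facts(
    kb: KnowledgeBase,
    matched_groups: Sequence[str],
    sections: Optional[dict[str, str]] = None,
    config: EhrConfig = DEFAULT_CONFIG,
) -> FactBundle:
    """Union of the matched groups' attached facts, deduplicated on
    (property, filler) keeping the most specific source, tagged with EHR
    sections via the property->section mapping."""
    mapping = sections if sections is not None else config.sections
    bundle = FactBundle()
    seen: set[tuple] = set()
    for group in matched_groups:
        for prop, filler in kb.final_facts_of(group):
            key = (prop.local_name, normalize(filler))
            if key in seen:
                continue
            seen.add(key)
            section = mapping.get(prop.local_name)
            if section is None:
                log.warning(
                    "property %s has no EHR section mapping; using %r",
                    prop,
                    DEFAULT_SECTION,
                )
                section = DEFAULT_SECTION
            bundle.entries.append(
                (group, prop.local_name, normalize(filler), section)
            )
    return bundle
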