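"""Fact-sheet authoring format: YAML (or JSON) compiled to a knowledge base.

Sections (all optional, validated on load):

- ``properties``: object properties, each ``{name, parent?, functional?,
  section?}``; ``section`` feeds the EHR property->section mapping.
- ``concepts``: atomic declarations ``{name, level?, provenance?, label?}``.
- ``hierarchy``: told subclass edges ``[sub, sup]``.
- ``disjoint``: lists of mutually disjoint class names.
- ``definitions``: defined classes ``{name, level?, equivalent_to: EXPR}``.
- ``facts``: final facts ``{subject, property, filler: EXPR}``.
- ``variants``: nomenclature events compiled through the composition module.
- ``pipelines``: bottom-up worked examples ``{change, group, anchor?,
  extra_conjuncts?, facts?}``.
- ``age_groups``: ``{intervals: [{name,min,max}], thresholds: [{name,min}]}``.
- ``ehr``: overrides for the matcher vocabulary (anchor class, property names).

EXPR is a class-expression literal: a bare name, ``{some: [property, EXPR]}``
or ``{and: [EXPR, ...]}``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional

import yaml

from .composition import (
    WorkedExample,
    CompositionStep,
    attach_final_fact,
    build_change_concept,
    build_patient_group,
    run_bottom_up_pipeline,
)
from .ehr import AgeGroupTable, DEFAULT_AGE_TABLE, EhrConfig
from .kb import (
    ClassExpression,
    ConceptId,
    Conjunction,
    DisjointClasses,
    Existential,
    KBError,
    KnowledgeBase,
    Named,
    SubClassOf,
    SubObjectPropertyOf,
    normalize,
)
from .nomenclature import (
    AminoAcidChange,
    Change,
    CompoundNucleotideEvent,
    NucleotideEvent,
    parse_label,
)


class FactSheetError(KBError):
    """Schema violation in a fact-sheet document."""


_SECTIONS = {
    "meta",
    "properties",
    "concepts",
    "hierarchy",
    "disjoint",
    "definitions",
    "facts",
    "variants",
    "pipelines",
    "age_groups",
    "ehr",
}


@dataclass
class CompiledFactSheet:
    kb: KnowledgeBase
    ehr_config: EhrConfig
    pipeline_steps: dict[str, list[CompositionStep]] = field(default_factory=dict)


def parse_expression(node: Any, where: str = "") -> ClassExpression:
    if isinstance(node, str):
        return Named(ConceptId(node))
    if isinstance(node, dict):
        if set(node) == {"some"}:
            spec = node["some"]
            if not (isinstance(spec, list) and len(spec) == 2):
                raise FactSheetError(f"{where}: 'some' needs [property, filler]")
            return Existential(ConceptId(spec[0]), parse_expression(spec[1], where))
        if set(node) == {"and"}:
            ops = node["and"]
            if not isinstance(ops, list) or len(ops) < 2:
                raise FactSheetError(f"{where}: 'and' needs >=2 operands")
            return normalize(
                Conjunction(tuple(parse_expression(o, where) for o in ops))
            )
        if "only" in node or "all" in node:
            raise FactSheetError(
                f"{where}: universal restrictions are not part of the format "
                "(only someValuesFrom is representable)"
            )
    raise FactSheetError(f"{where}: cannot parse expression {node!r}")


def _parse_change(node: dict, where: str) -> Change:
    if "label" in node:
        return parse_label(node["label"])
    kind = node.get("label_kind")
    if kind == "aa":
        return AminoAcidChange(int(node["position"]), node["from"], node["to"])
    if kind == "nt":
        return NucleotideEvent(
            node["kind"],
            int(node["position"]),
            intron_offset=node.get("intron_offset"),
            ref_bases=node.get("ref", ""),
            alt_bases=node.get("alt", ""),
        )
    if kind == "compound":
        return CompoundNucleotideEvent(
            int(node["position"]), node["ref"], node["alt"]
        )
    raise FactSheetError(f"{where}: unknown change spec {node!r}")


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise FactSheetError(msg)


def compile_factsheet(doc: dict) -> CompiledFactSheet:
    _require(isinstance(doc, dict), "fact sheet must be a mapping")
    unknown = set(doc) - _SECTIONS
    _require(not unknown, f"unknown fact-sheet sections: {sorted(unknown)}")

    kb = KnowledgeBase(name=str(doc.get("meta", {}).get("name", "kb")))
    sections_map: dict[str, str] = {}

    for i, p in enumerate(doc.get("properties", [])):
        _require(isinstance(p, dict) and "name" in p, f"properties[{i}]: need name")
        pid = ConceptId(p["name"])
        kb.declare_property(pid, functional=bool(p.get("functional", False)))
        if p.get("section"):
            sections_map[p["name"]] = p["section"]
    for i, p in enumerate(doc.get("properties", [])):
        if p.get("parent"):
            kb.add_axiom(
                SubObjectPropertyOf(ConceptId(p["name"]), ConceptId(p["parent"]))
            )

    for i, c in enumerate(doc.get("concepts", [])):
        _require(isinstance(c, dict) and "name" in c, f"concepts[{i}]: need name")
        anns = [("label", c["label"])] if c.get("label") else []
        kb.declare_concept(
            ConceptId(c["name"], c.get("provenance")),
            c.get("level", "basic"),
            annotations=anns,
        )

    for i, edge in enumerate(doc.get("hierarchy", [])):
        _require(
            isinstance(edge, list) and len(edge) == 2,
            f"hierarchy[{i}]: need [sub, sup]",
        )
        kb.add_axiom(
            SubClassOf(Named(ConceptId(edge[0])), Named(ConceptId(edge[1])))
        )

    for i, group in enumerate(doc.get("disjoint", [])):
        _require(
            isinstance(group, list) and len(group) >= 2,
            f"disjoint[{i}]: need >=2 classes",
        )
        kb.add_axiom(
            DisjointClasses(tuple(Named(ConceptId(n)) for n in group))
        )

    from .kb import EquivalentClasses  # local to avoid name shadowing above

    for i, d in enumerate(doc.get("definitions", [])):
        _require(
            isinstance(d, dict) and "name" in d and "equivalent_to" in d,
            f"definitions[{i}]: need name and equivalent_to",
        )
        cid = ConceptId(d["name"])
        if d["name"] not in kb.concepts:
            kb.declare_concept(cid, d.get("level", "complex"))
        body = parse_expression(d["equivalent_to"], f"definitions[{i}]")
        kb.add_axiom(EquivalentClasses(Named(cid), body))

    for i, v in enumerate(doc.get("variants", [])):
        build_change_concept(kb, _parse_change(v, f"variants[{i}]"))

    steps: dict[str, list[CompositionStep]] = {}
    for i, pl in enumerate(doc.get("pipelines", [])):
        _require(
            isinstance(pl, dict) and "change" in pl and "group" in pl,
            f"pipelines[{i}]: need change and group",
        )
        example = WorkedExample(
            change=_parse_change(pl["change"], f"pipelines[{i}].change"),
            group_name=pl["group"],
            anchor=pl.get("anchor", "Patient_CF"),
            extra_conjuncts=[
                (c["some"][0], parse_expression(c["some"][1]))
                for c in pl.get("extra_conjuncts", [])
            ],
            facts=[
                (f["property"], parse_expression(f["filler"]))
                for f in pl.get("facts", [])
            ],
            mutation_property=pl.get("mutation_property", "has_mutation"),
        )
        steps[pl["group"]] = run_bottom_up_pipeline(kb, example)

    for i, f in enumerate(doc.get("facts", [])):
        _require(
            isinstance(f, dict) and {"subject", "property", "filler"} <= set(f),
            f"facts[{i}]: need subject, property, filler",
        )
        attach_final_fact(
            kb,
            f["subject"],
            f["property"],
            parse_expression(f["filler"], f"facts[{i}]"),
        )

    age_table = DEFAULT_AGE_TABLE
    if "age_groups" in doc:
        ag = doc["age_groups"]
        age_table = AgeGroupTable(
            intervals=[
                (iv["name"], float(iv["min"]), None if iv.get("max") is None else float(iv["max"]))
                for iv in ag.get("intervals", [])
            ],
            thresholds=[
                (t["name"], float(t["min"])) for t in ag.get("thresholds", [])
            ],
        )

    ehr_over = doc.get("ehr", {})
    config = EhrConfig(
        anchor_class=ehr_over.get("anchor_class", "Patient"),
        diagnosis_property=ehr_over.get("diagnosis_property", "has_diagnosis"),
        sex_property=ehr_over.get("sex_property", "sex"),
        ethnicity_property=ehr_over.get("ethnicity_property", "ethnic_group"),
        age_property=ehr_over.get("age_property", "age_group"),
        mutation_property=ehr_over.get("mutation_property", "has_mutation"),
        age_table=age_table,
        sections=sections_map,
    )
    return CompiledFactSheet(kb=kb, ehr_config=config, pipeline_steps=steps)


def load_factsheet(path_or_text: str, is_text: bool = False) -> CompiledFactSheet:
    if is_text:
        text = path_or_text
    else:
        with open(path_or_text, "r") as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    return compile_factsheet(doc)
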