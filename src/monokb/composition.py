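"""Bottom-up construction: basic concepts -> combined concepts -> patient
groups -> final facts.

Variant concepts are placed under *every* applicable hierarchy (multi-parent
principle): a compound change like AA2183_minus_G sits under both the
deletion branch (Del_A, Nucleotide_deletion_in_human_CFTR_gene) and the
transition branch (A_transition_G, Nucleotide_transition_in_human_CFTR_gene).
Scaffold classes (Del_A, branch roots, position classes) are auto-created on
first use with a logged notice, since a fact sheet only ever enumerates a few
examples per mutation type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

from .kb import (
    ClassExpression,
    ConceptId,
    Conjunction,
    Existential,
    KBError,
    KnowledgeBase,
    Named,
    SubClassOf,
    EquivalentClasses,
    normalize,
)
from .nomenclature import (
    AminoAcidChange,
    Change,
    CompoundNucleotideEvent,
    NomenclatureConfig,
    DEFAULT_CONFIG,
    NucleotideEvent,
    build_label,
    canonical_name,
    classify_substitution,
)

log = logging.getLogger(__name__)

# scaffold vocabulary (paper-style names around the human CFTR gene/protein)
GENE = "Human_CFTR_gene"
CHAIN = "Human_CFTR_amino_acid_chain"
POSITION_ROOT = "Position_in_human_CFTR_amino_acid_chain"
AA_ROOT = "Amino_acid"
AA_SUBSTITUTION_ROOT = "Amino_acid_substitution_in_human_CFTR_amino_acid_chain"
NT_MUTATION_ROOT = "Nucleotide_mutation_in_human_CFTR_gene"
NT_BRANCH = {
    "deletion": "Nucleotide_deletion_in_human_CFTR_gene",
    "insertion": "Nucleotide_insertion_in_human_CFTR_gene",
    "substitution": "Nucleotide_substitution_in_human_CFTR_gene",
    "transition": "Nucleotide_transition_in_human_CFTR_gene",
    "transversion": "Nucleotide_transversion_in_human_CFTR_gene",
}
LOCATED_AT = "located_at"
ORIGINAL_AA = "original_amino_acid"
RESULTING_AA = "resulting_amino_acid"

PIPELINE_STAGES = (
    "basic",
    "combined_location",
    "combined_change",
    "complex_patient_group",
    "final_fact",
)


@dataclass
class CompositionStep:
    stage: str
    produced: str
    inputs: list[str] = field(default_factory=list)


class CoordinateError(KBError):
    """Non-positive sequence position."""


def _ensure_class(
    kb: KnowledgeBase, name: str, level: str = "basic", parents: Iterable[str] = ()
) -> ConceptId:
    cid = ConceptId(name)
    if name not in kb.concepts:
        log.info("auto-creating scaffold class %s", name)
        kb.declare_concept(cid, level)
    for p in parents:
        pid = _ensure_class(kb, p)
        kb.add_axiom(SubClassOf(Named(cid), Named(pid)))
    return cid


def _ensure_property(kb: KnowledgeBase, name: str) -> ConceptId:
    pid = ConceptId(name)
    if name not in kb.properties:
        log.info("auto-creating property %s", name)
        kb.declare_property(pid)
    return pid


# --------------------------------------------------------------------------
# combined concepts
# --------------------------------------------------------------------------


def build_location_concept(
    kb: KnowledgeBase, aa: ConceptId, position: int
) -> ConceptId:
    """A residue-at-position concept, e.g. Gly542 = Gly located at chain
    position 542. The position class keeps distinct locations logically
    distinct under classification."""
    if position <= 0:
        raise CoordinateError(f"position must be positive, got {position}")
    if aa.local_name not in kb.concepts:
        raise KBError(f"amino-acid concept {aa} not declared")
    name = f"{aa.local_name}{position}"
    cid = ConceptId(name)
    if name in kb.concepts:
        return cid
    if POSITION_ROOT not in kb.concepts:
        _ensure_class(kb, POSITION_ROOT)
        chain = _ensure_class(kb, CHAIN)
        kb.add_axiom(
            SubClassOf(
                Named(ConceptId(POSITION_ROOT)),
                Existential(_ensure_property(kb, "part_of"), Named(chain)),
            )
        )
    pos_cls = _ensure_class(kb, f"Position_{position}", parents=[POSITION_ROOT])
    prop = _ensure_property(kb, LOCATED_AT)
    kb.declare_concept(cid, "combined")
    kb.add_axiom(
        EquivalentClasses(
            Named(cid),
            normalize(
                Conjunction((Named(aa), Existential(prop, Named(pos_cls))))
            ),
        )
    )
    kb.add_axiom(SubClassOf(Named(cid), Named(aa)))
    return cid


def compute_parent_classes(
    event: Union[NucleotideEvent, CompoundNucleotideEvent]
) -> set[str]:
    """Every hierarchy a nucleotide event belongs under (multi-parent rule)."""
    if isinstance(event, CompoundNucleotideEvent):
        out: set[str] = set()
        for comp in event.components():
            out |= compute_parent_classes(comp)
        return out
    if event.kind == "deletion":
        parents = {f"Del_{b}" for b in set(event.ref_bases)}
        parents.add(NT_BRANCH["deletion"])
        return parents
    if event.kind == "insertion":
        parents = {f"Ins_{b}" for b in set(event.alt_bases)}
        parents.add(NT_BRANCH["insertion"])
        return parents
    # substitution
    if not event.alt_bases:
        return {NT_BRANCH["substitution"]}
    parents = set()
    for r, a in zip(event.ref_bases, event.alt_bases):
        if r == a:
            continue
        cls = classify_substitution(r, a).value
        parents.add(f"{r}_{cls}_{a}")
        parents.add(NT_BRANCH[cls])
    return parents


def _scaffold_branch(name: str) -> list[str]:
    """Branch root(s) a scaffold class like Del_A or A_transition_G sits under."""
    if name.startswith("Del_"):
        return [NT_BRANCH["deletion"]]
    if name.startswith("Ins_"):
        return [NT_BRANCH["insertion"]]
    if "_transition_" in name:
        return [NT_BRANCH["transition"]]
    if "_transversion_" in name:
        return [NT_BRANCH["transversion"]]
    return []


def build_change_concept(
    kb: KnowledgeBase,
    change: Change,
    config: NomenclatureConfig = DEFAULT_CONFIG,
) -> ConceptId:
    """Declare a variant concept under all applicable parents, with its
    HGVS-style canonical name kept as an annotation."""
    label = build_label(change, config)
    cid = ConceptId(label)
    if label in kb.concepts:
        return cid
    kb.declare_concept(cid, "combined", annotations=[("hgvs", canonical_name(change))])
    if isinstance(change, AminoAcidChange):
        aa_from = _ensure_class(kb, change.from_aa, parents=[AA_ROOT])
        if change.to_aa == "X":
            to_cls = _ensure_class(kb, "X")
        else:
            to_cls = _ensure_class(kb, change.to_aa, parents=[AA_ROOT])
        loc = build_location_concept(kb, aa_from, change.position)
        root = _ensure_class(kb, AA_SUBSTITUTION_ROOT)
        kb.add_axiom(SubClassOf(Named(cid), Named(root)))
        kb.add_axiom(
            EquivalentClasses(
                Named(cid),
                normalize(
                    Conjunction(
                        (
                            Named(root),
                            Existential(
                                _ensure_property(kb, ORIGINAL_AA), Named(loc)
                            ),
                            Existential(
                                _ensure_property(kb, RESULTING_AA), Named(to_cls)
                            ),
                        )
                    )
                ),
            )
        )
    else:
        for parent in sorted(compute_parent_classes(change)):
            branches = _scaffold_branch(parent)
            for b in branches:
                _ensure_class(kb, b, parents=[NT_MUTATION_ROOT])
            if parent in NT_BRANCH.values():
                _ensure_class(kb, parent, parents=[NT_MUTATION_ROOT])
            else:
                _ensure_class(kb, parent, parents=branches)
            kb.add_axiom(SubClassOf(Named(cid), Named(ConceptId(parent))))
    return cid


# --------------------------------------------------------------------------
# complex concepts (patient groups) and final facts
# --------------------------------------------------------------------------

PATIENT_ROOT = "Patient"

Conjunct = Union[str, ConceptId, tuple]


def build_patient_group(
    kb: KnowledgeBase,
    name: Union[str, ConceptId],
    conjuncts: Sequence[Conjunct],
    anchor_root: str = PATIENT_ROOT,
) -> ConceptId:
    """Define a patient group as an intersection of a patient/disease anchor
    with existential restrictions (only someValuesFrom is permitted)."""
    cid = ConceptId(name) if isinstance(name, str) else name
    if not conjuncts:
        raise KBError("a patient group needs at least one conjunct")
    ops: list[ClassExpression] = []
    has_anchor = False
    closure = None
    for c in conjuncts:
        if isinstance(c, (str, ConceptId)):
            cn = c if isinstance(c, str) else c.local_name
            if cn not in kb.concepts:
                raise KBError(f"undeclared conjunct class {cn}")
            ops.append(Named(ConceptId(cn)))
            if closure is None:
                from .reasoner import build_tells_closure

                closure = build_tells_closure(kb)
            anchored = closure.class_subsumed(cn, anchor_root) or (
                cn == anchor_root
            )
            # defined anchors (e.g. Patient_CF = Patient and ...) also count
            if not anchored:
                body = kb.definition_of(cn)
                if body is not None:
                    from .kb import iter_concept_refs

                    anchored = any(
                        closure.class_subsumed(r.local_name, anchor_root)
                        for r in iter_concept_refs(body)
                    )
            has_anchor = has_anchor or anchored
        elif isinstance(c, tuple) and len(c) == 2:
            prop, filler = c
            pid = ConceptId(prop) if isinstance(prop, str) else prop
            if pid.local_name not in kb.properties:
                raise KBError(f"undeclared property {pid}")
            if isinstance(filler, str):
                filler = Named(ConceptId(filler))
            ops.append(Existential(pid, filler))
        else:
            raise KBError(
                f"unsupported conjunct {c!r}: only named classes and "
                "(property, filler) existential pairs are allowed"
            )
    if not has_anchor:
        raise KBError(
            f"patient group {cid} lacks a {anchor_root}-rooted anchor conjunct"
        )
    if cid.local_name in kb.concepts:
        return cid
    kb.declare_concept(cid, "complex")
    body = normalize(Conjunction(tuple(ops))) if len(ops) > 1 else ops[0]
    kb.add_axiom(EquivalentClasses(Named(cid), body))
    return cid


def attach_final_fact(
    kb: KnowledgeBase,
    subject: Union[str, ConceptId],
    prop: Union[str, ConceptId],
    filler: Union[str, ClassExpression],
) -> KnowledgeBase:
    """Attach an existential property fact to a (complex) subject.

    The existential leaves the description open: a group having ``some``
    mutation Gly542X may well carry others. Non-complex subjects are allowed
    with a warning (level bookkeeping is metadata, not logic).
    """
    sid = ConceptId(subject) if isinstance(subject, str) else subject
    pid = ConceptId(prop) if isinstance(prop, str) else prop
    if isinstance(filler, str):
        filler = Named(ConceptId(filler))
    level = kb.level_of(sid.local_name)
    if level != "complex":
        log.warning(
            "final fact attached to %s, which is %s rather than complex",
            sid,
            level,
        )
    return kb.attach_final_fact(sid, pid, filler)


# --------------------------------------------------------------------------
# worked-example pipeline
# --------------------------------------------------------------------------


@dataclass
class WorkedExample:
    """One bottom-up construction run: a change, a patient group built on it,
    and the group's final facts."""

    change: Change
    group_name: str
    anchor: str = "Patient_CF"
    extra_conjuncts: list[tuple] = field(default_factory=list)
    facts: list[tuple] = field(default_factory=list)  # (property, filler)
    mutation_property: str = "has_mutation"


def run_bottom_up_pipeline(
    kb: KnowledgeBase,
    example: WorkedExample,
    config: NomenclatureConfig = DEFAULT_CONFIG,
) -> list[CompositionStep]:
    """Execute the six-stage construction chain and report each step.

    For an amino-acid change like Gly542X: Gly (basic), X (basic), Gly542
    (combined location), Gly542X (combined change), Patient_CF_with_Gly542X
    (complex group), then the group's final facts. Re-running on the same KB
    reports the steps again without adding axioms (idempotent).
    """
    steps: list[CompositionStep] = []
    ch = example.change
    if isinstance(ch, AminoAcidChange):
        _ensure_class(kb, ch.from_aa, parents=[AA_ROOT])
        steps.append(CompositionStep("basic", ch.from_aa))
        if ch.to_aa == "X":
            _ensure_class(kb, "X")
        else:
            _ensure_class(kb, ch.to_aa, parents=[AA_ROOT])
        steps.append(CompositionStep("basic", ch.to_aa))
        loc_name = f"{ch.from_aa}{ch.position}"
        build_location_concept(kb, ConceptId(ch.from_aa), ch.position)
        steps.append(
            CompositionStep("combined_location", loc_name, [ch.from_aa])
        )
        change_inputs = [loc_name, ch.to_aa]
    else:
        bases = sorted(
            set(
                (getattr(ch, "ref_bases", "") or "")
                + (getattr(ch, "alt_bases", "") or "")
            )
        )
        for b in bases:
            _ensure_class(kb, b, parents=["Nucleobase"])
            steps.append(CompositionStep("basic", b))
        change_inputs = bases
    label = build_label(ch, config)
    build_change_concept(kb, ch, config)
    steps.append(CompositionStep("combined_change", label, change_inputs))
    conj: list = [example.anchor, (example.mutation_property, label)]
    conj.extend(example.extra_conjuncts)
    build_patient_group(kb, example.group_name, conj)
    steps.append(
        CompositionStep(
            "complex_patient_group", example.group_name, [example.anchor, label]
        )
    )
    for prop, filler in example.facts:
        attach_final_fact(kb, example.group_name, prop, filler)
    steps.append(
        CompositionStep("final_fact", example.group_name, [example.group_name])
    )
    _check_dataflow(steps)
    return steps


def _check_dataflow(steps: list[CompositionStep]) -> None:
    """Inputs named by a step must have been produced strictly earlier
    (pre-existing scaffold/anchor classes are exempt)."""
    produced_at: dict[str, int] = {}
    for k, step in enumerate(steps):
        for inp in step.inputs:
            if inp in produced_at and produced_at[inp] >= k:
                raise KBError(
                    f"pipeline dataflow violation: step {k} uses {inp} "
                    "before it is produced"
                )
        produced_at.setdefault(step.produced, k)
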