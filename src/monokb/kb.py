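"""Core knowledge-base model: concepts, class expressions, axioms, container.

The representational fragment is deliberately small — named classes,
intersections, and existential restrictions (``someValuesFrom``) only — because
that is all a fact-sheet-driven genotype/phenotype knowledge base needs, and
restricting the fragment keeps structural reasoning sound and complete.
Universal restrictions and property domain/range axioms have no constructors
here at all; third-party files containing them are carried as opaque axioms by
the I/O layer and flagged by the audit.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Union

_NAME_RE = re.compile(r"^[A-Za-z0-9_]+$")
_CUI_RE = re.compile(r"^C\d{4,}$")


class KBError(Exception):
    """Base error for knowledge-base construction problems."""


class NamingError(KBError):
    """A concept name violates the alphanumeric-plus-underscore rule."""


class ConflictError(KBError):
    """Redeclaration of an entity with conflicting metadata."""


class DanglingReferenceError(KBError):
    """An axiom references an entity that was never declared."""


class CycleError(KBError):
    """Definitional cycle among defined classes."""


class AuditError(KBError):
    """The knowledge base violates a structural convention."""


# --------------------------------------------------------------------------
# identifiers
# --------------------------------------------------------------------------


@dataclass(frozen=True, eq=False)
class ConceptId:
    """Name of a class or object property.

    Identity is the OWL local name; ``provenance`` is carried as an annotation
    (a UMLS CUI such as ``C0010674``, a GO id, or ``"local"``) and does not
    participate in equality, matching OWL semantics where the IRI alone
    identifies an entity.
    """

    local_name: str
    provenance: Optional[str] = None

    def __post_init__(self) -> None:
        if not _NAME_RE.match(self.local_name):
            raise NamingError(
                f"invalid concept name {self.local_name!r}: only [A-Za-z0-9_] "
                "is allowed (special characters are encoded, e.g. plus/minus)"
            )

    @property
    def is_umls(self) -> bool:
        return bool(self.provenance and _CUI_RE.match(self.provenance))

    def __eq__(self, other: object) -> bool:
        if isinstance(other, ConceptId):
            return self.local_name == other.local_name
        return NotImplemented

    def __hash__(self) -> int:
        return hash(self.local_name)

    def __str__(self) -> str:
        return self.local_name


LEVELS = ("basic", "combined", "complex")


# --------------------------------------------------------------------------
# class expressions
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Named:
    concept: ConceptId

    def __str__(self) -> str:
        return self.concept.local_name


@dataclass(frozen=True)
class Existential:
    """ObjectSomeValuesFrom — the only restriction the fragment permits."""

    prop: ConceptId
    filler: "ClassExpression"

    def __str__(self) -> str:
        return f"(some {self.prop} {self.filler})"


@dataclass(frozen=True)
class Conjunction:
    operands: tuple["ClassExpression", ...]

    def __str__(self) -> str:
        return "(and " + " ".join(str(o) for o in self.operands) + ")"


ClassExpression = Union[Named, Existential, Conjunction]


def _expr_key(expr: ClassExpression) -> tuple:
    """Canonical sort key: named atoms before existentials, then lexicographic."""
    if isinstance(expr, Named):
        return (0, expr.concept.local_name)
    if isinstance(expr, Existential):
        return (1, expr.prop.local_name, _expr_key(expr.filler))
    return (2, tuple(_expr_key(o) for o in expr.operands))


def normalize(expr: ClassExpression) -> ClassExpression:
    """Flatten nested conjunctions, deduplicate and sort operands.

    Intersections are treated as sets of conjuncts; a singleton conjunction
    collapses to its operand. Normalized expressions compare with ``==``.
    """
    if isinstance(expr, Named):
        return expr
    if isinstance(expr, Existential):
        return Existential(expr.prop, normalize(expr.filler))
    flat: list[ClassExpression] = []
    seen: set = set()
    stack = list(expr.operands)
    while stack:
        op = stack.pop(0)
        if isinstance(op, Conjunction):
            stack = list(op.operands) + stack
            continue
        op = normalize(op)
        if op not in seen:
            seen.add(op)
            flat.append(op)
    if not flat:
        raise KBError("empty conjunction")
    if len(flat) == 1:
        return flat[0]
    flat.sort(key=_expr_key)
    return Conjunction(tuple(flat))


def expression_equal(a: ClassExpression, b: ClassExpression) -> bool:
    """Structural equality up to conjunction flattening/reordering."""
    return normalize(a) == normalize(b)


def conjuncts(expr: ClassExpression) -> tuple[ClassExpression, ...]:
    expr = normalize(expr)
    if isinstance(expr, Conjunction):
        return expr.operands
    return (expr,)


def iter_concept_refs(expr: ClassExpression) -> Iterator[ConceptId]:
    """All class names referenced in an expression (not property names)."""
    if isinstance(expr, Named):
        yield expr.concept
    elif isinstance(expr, Existential):
        yield from iter_concept_refs(expr.filler)
    else:
        for op in expr.operands:
            yield from iter_concept_refs(op)


def iter_property_refs(expr: ClassExpression) -> Iterator[ConceptId]:
    if isinstance(expr, Existential):
        yield expr.prop
        yield from iter_property_refs(expr.filler)
    elif isinstance(expr, Conjunction):
        for op in expr.operands:
            yield from iter_property_refs(op)


# --------------------------------------------------------------------------
# axioms
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Declaration:
    entity: ConceptId
    kind: str  # "class" | "object_property"


@dataclass(frozen=True)
class SubClassOf:
    sub: ClassExpression
    sup: ClassExpression


@dataclass(frozen=True)
class EquivalentClasses:
    a: ClassExpression
    b: ClassExpression


@dataclass(frozen=True)
class DisjointClasses:
    operands: tuple[ClassExpression, ...]


@dataclass(frozen=True)
class SubObjectPropertyOf:
    sub: ConceptId
    sup: ConceptId


@dataclass(frozen=True)
class AnnotationAssertion:
    subject: ConceptId
    prop: str  # "label" | "cui" | "hgvs" | "level"
    value: str


@dataclass(frozen=True)
class OpaqueAxiom:
    """An axiom outside the supported fragment, preserved verbatim for
    counting and round-tripping but invisible to inference."""

    text: str
    logical: bool = True


Axiom = Union[
    Declaration,
    SubClassOf,
    EquivalentClasses,
    DisjointClasses,
    SubObjectPropertyOf,
    AnnotationAssertion,
    OpaqueAxiom,
]

ANNOTATION_PROPS = ("label", "cui", "hgvs", "level")


def _axiom_key(ax: Axiom) -> tuple:
    if isinstance(ax, Declaration):
        return ("decl", ax.kind, ax.entity.local_name)
    if isinstance(ax, SubClassOf):
        return ("sub", _expr_key(normalize(ax.sub)), _expr_key(normalize(ax.sup)))
    if isinstance(ax, EquivalentClasses):
        keys = sorted([_expr_key(normalize(ax.a)), _expr_key(normalize(ax.b))])
        return ("equiv", tuple(keys))
    if isinstance(ax, DisjointClasses):
        keys = tuple(sorted(_expr_key(normalize(o)) for o in ax.operands))
        return ("disjoint", keys)
    if isinstance(ax, SubObjectPropertyOf):
        return ("subprop", ax.sub.local_name, ax.sup.local_name)
    if isinstance(ax, AnnotationAssertion):
        return ("ann", ax.subject.local_name, ax.prop, ax.value)
    return ("opaque", ax.text)


# --------------------------------------------------------------------------
# container
# --------------------------------------------------------------------------


@dataclass
class ConceptInfo:
    id: ConceptId
    level: str


@dataclass
class PropertyInfo:
    id: ConceptId
    functional: bool = False  # parsed/declared, never reasoned over by default


@dataclass
class FinalFact:
    """A defined subject plus its existential property facts."""

    subject: ConceptId
    definition: ClassExpression
    properties: list[tuple[ConceptId, ClassExpression]] = field(default_factory=list)


class KnowledgeBase:
    """Concepts, object properties and an ordered, set-like axiom list."""

    def __init__(self, name: str = "kb") -> None:
        self.name = name
        self.concepts: dict[str, ConceptInfo] = {}
        self.properties: dict[str, PropertyInfo] = {}
        self.axioms: list[Axiom] = []
        self.individual_count = 0  # only ever nonzero for parsed foreign files
        self._axiom_keys: set[tuple] = set()

    # -- declarations ------------------------------------------------------

    def declare_concept(
        self,
        id: ConceptId,
        level: str = "basic",
        annotations: Iterable[tuple[str, str]] = (),
    ) -> "KnowledgeBase":
        if level not in LEVELS:
            raise KBError(f"unknown concept level {level!r}")
        existing = self.concepts.get(id.local_name)
        if existing is not None:
            if existing.level != level:
                raise ConflictError(
                    f"{id.local_name} already declared with level "
                    f"{existing.level!r}, not {level!r}"
                )
            return self
        if id.local_name in self.properties:
            raise ConflictError(f"{id.local_name} already declared as a property")
        self.concepts[id.local_name] = ConceptInfo(id, level)
        self._append(Declaration(id, "class"))
        self._append(AnnotationAssertion(id, "level", level))
        if id.is_umls:
            self._append(AnnotationAssertion(id, "cui", id.provenance))
        for prop, value in annotations:
            if prop not in ANNOTATION_PROPS:
                raise KBError(f"unsupported annotation property {prop!r}")
            self._append(AnnotationAssertion(id, prop, value))
        return self

    def declare_property(
        self, id: ConceptId, functional: bool = False
    ) -> "KnowledgeBase":
        existing = self.properties.get(id.local_name)
        if existing is not None:
            if functional:
                existing.functional = True
            return self
        if id.local_name in self.concepts:
            raise ConflictError(f"{id.local_name} already declared as a class")
        self.properties[id.local_name] = PropertyInfo(id, functional)
        self._append(Declaration(id, "object_property"))
        return self

    # -- axioms ------------------------------------------------------------

    def _append(self, ax: Axiom) -> bool:
        key = _axiom_key(ax)
        if key in self._axiom_keys:
            return False
        self._axiom_keys.add(key)
        self.axioms.append(ax)
        return True

    def add_axiom(self, ax: Axiom) -> "KnowledgeBase":
        self._check_refs(ax)
        self._append(ax)
        return self

    def _check_refs(self, ax: Axiom) -> None:
        exprs: list[ClassExpression] = []
        if isinstance(ax, SubClassOf):
            exprs = [ax.sub, ax.sup]
        elif isinstance(ax, EquivalentClasses):
            exprs = [ax.a, ax.b]
        elif isinstance(ax, DisjointClasses):
            exprs = list(ax.operands)
        elif isinstance(ax, SubObjectPropertyOf):
            for p in (ax.sub, ax.sup):
                if p.local_name not in self.properties:
                    raise DanglingReferenceError(f"undeclared property {p}")
            return
        elif isinstance(ax, AnnotationAssertion):
            if (
                ax.subject.local_name not in self.concepts
                and ax.subject.local_name not in self.properties
            ):
                raise DanglingReferenceError(f"undeclared entity {ax.subject}")
            return
        else:
            return
        for expr in exprs:
            for c in iter_concept_refs(expr):
                if c.local_name not in self.concepts:
                    raise DanglingReferenceError(f"undeclared class {c}")
            for p in iter_property_refs(expr):
                if p.local_name not in self.properties:
                    raise DanglingReferenceError(f"undeclared property {p}")

    # -- views -------------------------------------------------------------

    def level_of(self, name: str) -> Optional[str]:
        info = self.concepts.get(name)
        return info.level if info else None

    def definition_of(self, name: str) -> Optional[ClassExpression]:
        """The EquivalentClasses body of a defined named class, if any."""
        for ax in self.axioms:
            if isinstance(ax, EquivalentClasses):
                if isinstance(ax.a, Named) and ax.a.concept.local_name == name:
                    return ax.b
                if isinstance(ax.b, Named) and ax.b.concept.local_name == name:
                    return ax.a
        return None

    def told_superclasses(self, name: str) -> list[ClassExpression]:
        """Asserted (SubClassOf) superclass expressions of a named class."""
        out = []
        for ax in self.axioms:
            if (
                isinstance(ax, SubClassOf)
                and isinstance(ax.sub, Named)
                and ax.sub.concept.local_name == name
            ):
                out.append(ax.sup)
        return out

    def told_parents(self, name: str) -> list[str]:
        """Named told superclasses only."""
        return [
            sup.concept.local_name
            for sup in self.told_superclasses(name)
            if isinstance(sup, Named)
        ]

    def annotations_of(self, name: str) -> list[tuple[str, str]]:
        return [
            (ax.prop, ax.value)
            for ax in self.axioms
            if isinstance(ax, AnnotationAssertion)
            and ax.subject.local_name == name
        ]

    def disjoint_pairs(self) -> list[tuple[ClassExpression, ClassExpression]]:
        pairs = []
        for ax in self.axioms:
            if isinstance(ax, DisjointClasses):
                ops = ax.operands
                for i in range(len(ops)):
                    for j in range(i + 1, len(ops)):
                        pairs.append((ops[i], ops[j]))
        return pairs

    def attach_final_fact(
        self, subject: ConceptId, prop: ConceptId, filler: ClassExpression
    ) -> "KnowledgeBase":
        return self.add_axiom(SubClassOf(Named(subject), Existential(prop, filler)))

    def final_facts_of(self, name: str) -> list[tuple[ConceptId, ClassExpression]]:
        """Existential SubClassOf facts attached to a named class."""
        out = []
        for sup in self.told_superclasses(name):
            if isinstance(sup, Existential):
                out.append((sup.prop, sup.filler))
        return out

    # -- audit -------------------------------------------------------------

    def audit(self) -> list[str]:
        """Structural conventions check; empty list means clean.

        Checks: no out-of-fragment opaque axioms, UMLS concepts carry exactly
        one CUI, declaration bookkeeping, no told subclass cycles among named
        classes (equivalences aside), no definitional cycles, at most one
        definition per named class.
        """
        issues: list[str] = []
        for ax in self.axioms:
            if isinstance(ax, OpaqueAxiom):
                issues.append(f"out-of-fragment axiom preserved opaquely: {ax.text}")
        for info in self.concepts.values():
            if info.id.is_umls:
                cuis = [v for p, v in self.annotations_of(info.id.local_name) if p == "cui"]
                if len(cuis) != 1:
                    issues.append(
                        f"{info.id} is UMLS-sourced but carries {len(cuis)} CUI annotations"
                    )
        n_decl = sum(1 for ax in self.axioms if isinstance(ax, Declaration))
        if n_decl != len(self.concepts) + len(self.properties):
            issues.append("declaration count does not match entity count")
        defined: dict[str, int] = {}
        for ax in self.axioms:
            if isinstance(ax, EquivalentClasses):
                for side in (ax.a, ax.b):
                    if isinstance(side, Named):
                        defined[side.concept.local_name] = (
                            defined.get(side.concept.local_name, 0) + 1
                        )
        for name, n in defined.items():
            if n > 1:
                issues.append(f"{name} has {n} EquivalentClasses definitions")
        issues.extend(self._cycle_issues())
        return issues

    def _cycle_issues(self) -> list[str]:
        import networkx as nx

        told = nx.DiGraph()
        told.add_nodes_from(self.concepts)
        uses = nx.DiGraph()
        uses.add_nodes_from(self.concepts)
        for ax in self.axioms:
            if isinstance(ax, SubClassOf) and isinstance(ax.sub, Named):
                if isinstance(ax.sup, Named):
                    told.add_edge(ax.sub.concept.local_name, ax.sup.concept.local_name)
            elif isinstance(ax, EquivalentClasses):
                for side, body in ((ax.a, ax.b), (ax.b, ax.a)):
                    if isinstance(side, Named) and not isinstance(body, Named):
                        for ref in iter_concept_refs(body):
                            uses.add_edge(side.concept.local_name, ref.local_name)
        issues = []
        if not nx.is_directed_acyclic_graph(told):
            cyc = next(iter(nx.simple_cycles(told)))
            issues.append("told subclass cycle: " + " -> ".join(cyc))
        if not nx.is_directed_acyclic_graph(uses):
            cyc = next(iter(nx.simple_cycles(uses)))
            issues.append("definitional cycle: " + " -> ".join(cyc))
        return issues
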