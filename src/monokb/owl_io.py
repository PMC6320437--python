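"""OWL 2 serialization (functional syntax), parsing (functional syntax and
RDF/XML) and ontology metrics.

The writer emits only the fragment the knowledge base can hold — class and
object-property declarations, SubClassOf, EquivalentClasses, DisjointClasses,
SubObjectPropertyOf, annotation assertions, ObjectIntersectionOf and
ObjectSomeValuesFrom — in a deterministic order, so two writes of the same KB
are byte-identical. Readers preserve out-of-fragment constructs (universal
restrictions, domain/range, inverse/functional declarations, individuals) as
opaque axioms so that metrics over third-party files still count everything,
and the audit flags them.
"""

from __future__ import annotations

import math
import re
from dataclasses import asdict, dataclass

import networkx as nx

from .kb import (
    AnnotationAssertion,
    Axiom,
    ClassExpression,
    ConceptId,
    Conjunction,
    Declaration,
    DisjointClasses,
    EquivalentClasses,
    Existential,
    KBError,
    KnowledgeBase,
    Named,
    OpaqueAxiom,
    SubClassOf,
    SubObjectPropertyOf,
    _axiom_key,
    normalize,
)

BASE_IRI = "http://example.org/monokb#"
ONTOLOGY_IRI = "http://example.org/monokb"

_PREFIXES = [
    ("", BASE_IRI),
    ("owl", "http://www.w3.org/2002/07/owl#"),
    ("rdf", "http://www.w3.org/1999/02/22-rdf-syntax-ns#"),
    ("rdfs", "http://www.w3.org/2000/01/rdf-schema#"),
    ("xsd", "http://www.w3.org/2001/XMLSchema#"),
]

_ANN_IRI = {
    "label": "rdfs:label",
    "cui": ":cui",
    "hgvs": ":hgvs",
    "level": ":level",
}
_IRI_ANN = {v: k for k, v in _ANN_IRI.items()}


class OwlParseError(KBError):
    """Malformed OWL document (message includes the offending location)."""


class SerializationError(KBError):
    """Expression outside the supported fragment."""


# --------------------------------------------------------------------------
# writing
# --------------------------------------------------------------------------


def _render_expr(expr: ClassExpression) -> str:
    if isinstance(expr, Named):
        return f":{expr.concept.local_name}"
    if isinstance(expr, Existential):
        return (
            f"ObjectSomeValuesFrom(:{expr.prop.local_name} "
            f"{_render_expr(expr.filler)})"
        )
    if isinstance(expr, Conjunction):
        return (
            "ObjectIntersectionOf("
            + " ".join(_render_expr(o) for o in expr.operands)
            + ")"
        )
    raise SerializationError(f"cannot serialize {expr!r}")


def _render_axiom(ax: Axiom) -> str:
    if isinstance(ax, Declaration):
        kind = "Class" if ax.kind == "class" else "ObjectProperty"
        return f"Declaration({kind}(:{ax.entity.local_name}))"
    if isinstance(ax, SubClassOf):
        return (
            f"SubClassOf({_render_expr(normalize(ax.sub))} "
            f"{_render_expr(normalize(ax.sup))})"
        )
    if isinstance(ax, EquivalentClasses):
        return (
            f"EquivalentClasses({_render_expr(normalize(ax.a))} "
            f"{_render_expr(normalize(ax.b))})"
        )
    if isinstance(ax, DisjointClasses):
        ops = sorted(_render_expr(normalize(o)) for o in ax.operands)
        return "DisjointClasses(" + " ".join(ops) + ")"
    if isinstance(ax, SubObjectPropertyOf):
        return f"SubObjectPropertyOf(:{ax.sub.local_name} :{ax.sup.local_name})"
    if isinstance(ax, AnnotationAssertion):
        value = ax.value.replace("\\", "\\\\").replace('"', '\\"')
        return (
            f"AnnotationAssertion({_ANN_IRI[ax.prop]} "
            f":{ax.subject.local_name} \"{value}\")"
        )
    if isinstance(ax, OpaqueAxiom):
        return ax.text
    raise SerializationError(f"cannot serialize axiom {ax!r}")


_ORDER = {
    Declaration: 0,
    SubObjectPropertyOf: 1,
    SubClassOf: 2,
    EquivalentClasses: 3,
    DisjointClasses: 4,
    AnnotationAssertion: 5,
    OpaqueAxiom: 6,
}


def write_owl(kb: KnowledgeBase) -> str:
    """Deterministic OWL 2 functional-syntax document."""
    lines = [f"Prefix({p}:=<{iri}>)" for p, iri in _PREFIXES]
    lines.append(f"Ontology(<{ONTOLOGY_IRI}>")
    rendered = sorted(
        kb.axioms, key=lambda ax: (_ORDER[type(ax)], _axiom_key(ax))
    )
    lines.extend(_render_axiom(ax) for ax in rendered)
    lines.append(")")
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# functional-syntax reading
# --------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"""\s*(?:
        (?P<lparen>\() |
        (?P<rparen>\)) |
        (?P<string>"(?:[^"\\]|\\.)*") |
        (?P<iri><[^>]*>) |
        (?P<name>[^\s()"<>]+)
    )""",
    re.VERBOSE,
)


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens = []
    pos = 0
    line = 1
    while pos < len(text):
        if text[pos:].isspace():
            break
        m = _TOKEN_RE.match(text, pos)
        if not m:
            raise OwlParseError(f"line {line}: unexpected character {text[pos]!r}")
        line += text.count("\n", pos, m.end())
        pos = m.end()
        kind = m.lastgroup
        tokens.append((kind, m.group(kind), line))
    return tokens


_FRAGMENT_HEADS = {
    "Declaration",
    "SubClassOf",
    "EquivalentClasses",
    "DisjointClasses",
    "SubObjectPropertyOf",
    "AnnotationAssertion",
}
_LOGICAL_HEADS = {
    "SubClassOf",
    "EquivalentClasses",
    "DisjointClasses",
    "DisjointUnion",
    "SubObjectPropertyOf",
    "EquivalentObjectProperties",
    "DisjointObjectProperties",
    "InverseObjectProperties",
    "ObjectPropertyDomain",
    "ObjectPropertyRange",
    "FunctionalObjectProperty",
    "InverseFunctionalObjectProperty",
    "TransitiveObjectProperty",
    "SymmetricObjectProperty",
    "ClassAssertion",
    "ObjectPropertyAssertion",
    "SameIndividual",
    "DifferentIndividuals",
}


_OUT_OF_FRAGMENT_EXPRS = {
    "ObjectAllValuesFrom",
    "ObjectUnionOf",
    "ObjectComplementOf",
    "ObjectOneOf",
    "ObjectHasValue",
    "ObjectHasSelf",
    "ObjectMinCardinality",
    "ObjectMaxCardinality",
    "ObjectExactCardinality",
    "DataSomeValuesFrom",
    "DataAllValuesFrom",
    "DataHasValue",
}


class _OutOfFragmentExpression(Exception):
    """Well-formed OWL, but outside the existential-conjunctive fragment."""


class _FSParser:
    def __init__(self, text: str):
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self):
        tok = self.peek()
        if tok is None:
            raise OwlParseError("unexpected end of document")
        self.i += 1
        return tok

    def expect(self, kind):
        tok = self.next()
        if tok[0] != kind:
            raise OwlParseError(f"line {tok[2]}: expected {kind}, got {tok[1]!r}")
        return tok

    def local(self, name: str, line: int) -> str:
        if name.startswith(":"):
            return name[1:]
        if name.startswith("<") and name.endswith(">"):
            return _iri_local(name[1:-1])
        if ":" in name:
            return name.split(":", 1)[1]
        raise OwlParseError(f"line {line}: cannot resolve entity {name!r}")

    # -- balanced raw capture for opaque axioms --

    def capture_balanced(self, start: int) -> str:
        depth = 0
        parts = []
        i = start
        while i < len(self.tokens):
            kind, val, _ = self.tokens[i]
            if kind == "lparen":
                depth += 1
                parts.append("(")
            elif kind == "rparen":
                depth -= 1
                parts.append(")")
            else:
                if parts and parts[-1] not in "(":
                    parts.append(" ")
                parts.append(val)
            i += 1
            if depth == 0 and i > start + 1:
                break
        self.i = i
        return "".join(parts)

    def parse_expression(self) -> ClassExpression:
        kind, val, line = self.next()
        if kind == "name" and val in _OUT_OF_FRAGMENT_EXPRS:
            raise _OutOfFragmentExpression(val)
        if kind == "name" and val not in (
            "ObjectIntersectionOf",
            "ObjectSomeValuesFrom",
        ):
            return Named(ConceptId(self.local(val, line)))
        if kind == "iri":
            return Named(ConceptId(_iri_local(val[1:-1])))
        if val == "ObjectIntersectionOf":
            self.expect("lparen")
            ops = []
            while self.peek() and self.peek()[0] != "rparen":
                ops.append(self.parse_expression())
            self.expect("rparen")
            return Conjunction(tuple(ops))
        if val == "ObjectSomeValuesFrom":
            self.expect("lparen")
            pkind, pval, pline = self.next()
            prop = ConceptId(self.local(pval, pline))
            filler = self.parse_expression()
            self.expect("rparen")
            return Existential(prop, filler)
        if val in _OUT_OF_FRAGMENT_EXPRS:
            raise _OutOfFragmentExpression(val)
        raise OwlParseError(f"line {line}: unsupported class expression {val!r}")


def _iri_local(iri: str) -> str:
    frag = iri.rsplit("#", 1)[-1].rsplit("/", 1)[-1]
    return re.sub(r"[^A-Za-z0-9_]", "_", frag) or "unnamed"


def read_owl_functional(text: str) -> KnowledgeBase:
    p = _FSParser(text)
    kb = KnowledgeBase()
    decls: list[tuple[str, str]] = []  # (kind, name)
    pending: list[Axiom] = []
    opaque: list[OpaqueAxiom] = []
    while p.peek() is not None:
        kind, val, line = p.peek()
        if kind == "rparen":  # closing the Ontology(...) block
            p.next()
            continue
        if kind != "name":
            raise OwlParseError(f"line {line}: expected axiom, got {val!r}")
        if val in ("Prefix", "Ontology"):
            p.next()
            if val == "Prefix":
                p.capture_balanced(p.i)
            else:
                p.expect("lparen")
                while p.peek() and p.peek()[0] == "iri":
                    p.next()
            continue
        if val == ")":  # not produced by tokenizer as name; safety
            p.next()
            continue
        if val not in _FRAGMENT_HEADS:
            raw = p.capture_balanced(p.i)
            opaque.append(OpaqueAxiom(raw, logical=val in _LOGICAL_HEADS))
            continue
        start = p.i
        try:
            _parse_fragment_axiom(p, val, kb, decls, pending, opaque)
        except _OutOfFragmentExpression:
            p.i = start
            raw = p.capture_balanced(p.i)
            opaque.append(OpaqueAxiom(raw, logical=val in _LOGICAL_HEADS))
    _finish_kb(kb, decls, pending, opaque)
    return kb


def _parse_fragment_axiom(p, val, kb, decls, pending, opaque) -> None:
        p.next()
        p.expect("lparen")
        if val == "Declaration":
            dkind, dval, dline = p.next()
            p.expect("lparen")
            ekind, ename, eline = p.next()
            name = p.local(ename, eline)
            p.expect("rparen")
            p.expect("rparen")
            if dval == "Class":
                decls.append(("class", name))
            elif dval == "ObjectProperty":
                decls.append(("object_property", name))
            elif dval == "NamedIndividual":
                kb.individual_count += 1
                opaque.append(
                    OpaqueAxiom(f"Declaration(NamedIndividual(:{name}))", False)
                )
            else:
                opaque.append(OpaqueAxiom(f"Declaration({dval}(:{name}))", False))
        elif val == "SubClassOf":
            sub = p.parse_expression()
            sup = p.parse_expression()
            p.expect("rparen")
            pending.append(SubClassOf(sub, sup))
        elif val == "EquivalentClasses":
            exprs = []
            while p.peek() and p.peek()[0] != "rparen":
                exprs.append(p.parse_expression())
            p.expect("rparen")
            for other in exprs[1:]:
                pending.append(EquivalentClasses(exprs[0], other))
        elif val == "DisjointClasses":
            exprs = []
            while p.peek() and p.peek()[0] != "rparen":
                exprs.append(p.parse_expression())
            p.expect("rparen")
            pending.append(DisjointClasses(tuple(exprs)))
        elif val == "SubObjectPropertyOf":
            k1, v1, l1 = p.next()
            k2, v2, l2 = p.next()
            p.expect("rparen")
            pending.append(
                SubObjectPropertyOf(
                    ConceptId(p.local(v1, l1)), ConceptId(p.local(v2, l2))
                )
            )
        elif val == "AnnotationAssertion":
            k1, v1, l1 = p.next()  # annotation property
            k2, v2, l2 = p.next()  # subject
            k3, v3, l3 = p.next()  # value (string literal)
            p.expect("rparen")
            prop = _IRI_ANN.get(v1)
            subject = p.local(v2, l2)
            if k3 != "string" or prop is None:
                opaque.append(
                    OpaqueAxiom(
                        f"AnnotationAssertion({v1} {v2} {v3})", logical=False
                    )
                )
                return
            value = v3[1:-1].replace('\\"', '"').replace("\\\\", "\\")
            pending.append(
                AnnotationAssertion(ConceptId(subject), prop, value)
            )


def _finish_kb(
    kb: KnowledgeBase,
    decls: list[tuple[str, str]],
    pending: list[Axiom],
    opaque: list[OpaqueAxiom],
) -> None:
    """Declare entities (explicit, then implicitly used), then add axioms."""
    from .kb import iter_concept_refs, iter_property_refs

    level_ann: dict[str, str] = {}
    for ax in pending:
        if isinstance(ax, AnnotationAssertion) and ax.prop == "level":
            level_ann[ax.subject.local_name] = ax.value
    for kind, name in decls:
        if kind == "class":
            kb.declare_concept(ConceptId(name), level_ann.get(name, "basic"))
        else:
            kb.declare_property(ConceptId(name))
    exprs: list[ClassExpression] = []
    for ax in pending:
        if isinstance(ax, SubClassOf):
            exprs += [ax.sub, ax.sup]
        elif isinstance(ax, EquivalentClasses):
            exprs += [ax.a, ax.b]
        elif isinstance(ax, DisjointClasses):
            exprs += list(ax.operands)
        elif isinstance(ax, SubObjectPropertyOf):
            kb.declare_property(ax.sub)
            kb.declare_property(ax.sup)
    for expr in exprs:
        for c in iter_concept_refs(expr):
            if c.local_name not in kb.concepts:
                kb.declare_concept(c, level_ann.get(c.local_name, "basic"))
        for pr in iter_property_refs(expr):
            kb.declare_property(pr)
    for ax in pending:
        if isinstance(ax, AnnotationAssertion):
            if (
                ax.subject.local_name not in kb.concepts
                and ax.subject.local_name not in kb.properties
            ):
                kb.declare_concept(ax.subject, level_ann.get(ax.subject.local_name, "basic"))
            # level annotations are re-created by declare_concept
            if ax.prop == "level":
                continue
        kb.add_axiom(ax)
    for op in opaque:
        kb._append(op)


# --------------------------------------------------------------------------
# RDF/XML reading (rdflib)
# --------------------------------------------------------------------------


def read_owl_rdfxml(text: str) -> KnowledgeBase:
    import rdflib
    from rdflib import RDF, RDFS, OWL
    from rdflib.term import BNode, Literal, URIRef

    g = rdflib.Graph()
    try:
        g.parse(data=text, format="xml")
    except Exception as exc:  # rdflib raises assorted parser errors
        raise OwlParseError(f"malformed RDF/XML: {exc}") from exc

    kb = KnowledgeBase()
    pending: list[Axiom] = []
    opaque: list[OpaqueAxiom] = []

    class _OutOfFragment(Exception):
        pass

    def expr_of(node):
        if isinstance(node, URIRef):
            if node == OWL.Thing:
                return None
            return Named(ConceptId(_iri_local(str(node))))
        if isinstance(node, BNode):
            some = g.value(node, OWL.someValuesFrom)
            on_prop = g.value(node, OWL.onProperty)
            if some is not None and on_prop is not None:
                filler = expr_of(some)
                if filler is None:
                    raise _OutOfFragment("someValuesFrom owl:Thing")
                return Existential(ConceptId(_iri_local(str(on_prop))), filler)
            if g.value(node, OWL.allValuesFrom) is not None:
                raise _OutOfFragment("ObjectAllValuesFrom")
            inter = g.value(node, OWL.intersectionOf)
            if inter is not None:
                ops = []
                for item in g.items(inter):
                    sub = expr_of(item)
                    if sub is not None:
                        ops.append(sub)
                return Conjunction(tuple(ops))
            raise _OutOfFragment("unsupported anonymous class")
        raise _OutOfFragment(f"unsupported node {node!r}")

    decls: list[tuple[str, str]] = []
    for s in g.subjects(RDF.type, OWL.Class):
        if isinstance(s, URIRef):
            decls.append(("class", _iri_local(str(s))))
    for s in g.subjects(RDF.type, OWL.ObjectProperty):
        if isinstance(s, URIRef):
            decls.append(("object_property", _iri_local(str(s))))
    for s in g.subjects(RDF.type, OWL.NamedIndividual):
        kb.individual_count += 1
        opaque.append(OpaqueAxiom(f"NamedIndividual({s})", logical=False))

    def add_or_flag(make, context):
        try:
            pending.append(make())
        except _OutOfFragment as exc:
            opaque.append(OpaqueAxiom(f"{context}: {exc}", logical=True))

    for s, o in g.subject_objects(RDFS.subClassOf):
        if not isinstance(s, URIRef) or s == OWL.Thing:
            continue
        try:
            sup = expr_of(o)
        except _OutOfFragment as exc:
            opaque.append(OpaqueAxiom(f"SubClassOf({s}): {exc}", logical=True))
            continue
        if sup is not None:  # rdfs:subClassOf owl:Thing is vacuous
            pending.append(SubClassOf(expr_of(s), sup))
    for s, o in g.subject_objects(OWL.equivalentClass):
        if isinstance(s, URIRef):
            add_or_flag(
                lambda s=s, o=o: EquivalentClasses(expr_of(s), expr_of(o)),
                f"EquivalentClasses({s})",
            )
    for s, o in g.subject_objects(OWL.disjointWith):
        add_or_flag(
            lambda s=s, o=o: DisjointClasses((expr_of(s), expr_of(o))),
            f"DisjointClasses({s})",
        )
    for s, o in g.subject_objects(RDFS.subPropertyOf):
        if isinstance(s, URIRef) and isinstance(o, URIRef):
            pending.append(
                SubObjectPropertyOf(
                    ConceptId(_iri_local(str(s))), ConceptId(_iri_local(str(o)))
                )
            )
    ann_props = {
        RDFS.label: "label",
        URIRef(BASE_IRI + "cui"): "cui",
        URIRef(BASE_IRI + "hgvs"): "hgvs",
        URIRef(BASE_IRI + "level"): "level",
    }
    for pred, name in ann_props.items():
        for s, o in g.subject_objects(pred):
            if isinstance(s, URIRef) and isinstance(o, Literal):
                pending.append(
                    AnnotationAssertion(
                        ConceptId(_iri_local(str(s))), name, str(o)
                    )
                )
    for pred in (OWL.inverseOf,):
        for s, o in g.subject_objects(pred):
            opaque.append(OpaqueAxiom(f"InverseObjectProperties({s} {o})"))
    functional_names = []
    for s in g.subjects(RDF.type, OWL.FunctionalProperty):
        name = _iri_local(str(s))
        functional_names.append(name)
        opaque.append(OpaqueAxiom(f"FunctionalObjectProperty(:{name})"))
    _finish_kb(kb, decls, pending, opaque)
    for name in functional_names:
        if name in kb.properties:
            kb.properties[name].functional = True
    return kb


def read_owl(text: str) -> KnowledgeBase:
    """Parse a supported OWL dialect, auto-detected."""
    stripped = text.lstrip()
    if stripped.startswith("<"):
        return read_owl_rdfxml(text)
    return read_owl_functional(text)


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------


@dataclass
class OntologyMetrics:
    """Entity and axiom counts in the ontology-editor convention: "axiom"
    counts everything including declarations and annotations; "logical axiom"
    excludes both; an n-ary EquivalentClasses/DisjointClasses counts once."""

    axiom_count: int
    logical_axiom_count: int
    declaration_count: int
    class_count: int
    individual_count: int
    object_property_count: int
    subclassof_count: int
    equivalentclasses_count: int
    disjointclasses_count: int
    annotation_assertion_count: int
    max_depth: int  # asserted edges from the top concept
    max_depth_nodes: int  # same path measured in named-class nodes
    max_children: int
    avg_children: int  # rounded to nearest integer
    avg_children_exact: float
    single_child_classes: int

    def as_dict(self) -> dict:
        return asdict(self)


def _asserted_child_graph(kb: KnowledgeBase) -> nx.DiGraph:
    """parent -> child edges over asserted named SubClassOf (definitions'
    named conjuncts are not asserted edges); unrooted classes attach to top."""
    g = nx.DiGraph()
    g.add_node("__top__")
    g.add_nodes_from(kb.concepts)
    for ax in kb.axioms:
        if (
            isinstance(ax, SubClassOf)
            and isinstance(ax.sub, Named)
            and isinstance(ax.sup, Named)
        ):
            g.add_edge(ax.sup.concept.local_name, ax.sub.concept.local_name)
    for name in kb.concepts:
        if g.in_degree(name) == 0:
            g.add_edge("__top__", name)
    if not nx.is_directed_acyclic_graph(g):
        # cycles (equivalence loops in foreign files): collapse for stats
        g = nx.condensation(g)
        mapping = {n: "+".join(map(str, d["members"])) for n, d in g.nodes(data=True)}
        g = nx.relabel_nodes(g, mapping)
    return g


def compute_metrics(kb: KnowledgeBase) -> OntologyMetrics:
    n_decl = sum(1 for ax in kb.axioms if isinstance(ax, Declaration))
    n_sub = sum(1 for ax in kb.axioms if isinstance(ax, SubClassOf))
    n_eq = sum(1 for ax in kb.axioms if isinstance(ax, EquivalentClasses))
    n_dis = sum(1 for ax in kb.axioms if isinstance(ax, DisjointClasses))
    n_subprop = sum(1 for ax in kb.axioms if isinstance(ax, SubObjectPropertyOf))
    n_ann = sum(1 for ax in kb.axioms if isinstance(ax, AnnotationAssertion))
    n_opq_logical = sum(
        1 for ax in kb.axioms if isinstance(ax, OpaqueAxiom) and ax.logical
    )
    n_opq_other = sum(
        1 for ax in kb.axioms if isinstance(ax, OpaqueAxiom) and not ax.logical
    )
    logical = n_sub + n_eq + n_dis + n_subprop + n_opq_logical
    total = logical + n_decl + n_ann + n_opq_other

    g = _asserted_child_graph(kb)
    if len(g) > 1:
        depth = nx.dag_longest_path_length(g)
    else:
        depth = 0
    counts = [
        g.out_degree(n) for n in g.nodes if n != "__top__" and g.out_degree(n) > 0
    ]
    max_children = max(counts) if counts else 0
    avg_exact = (sum(counts) / len(counts)) if counts else 0.0
    single = sum(1 for c in counts if c == 1)
    return OntologyMetrics(
        axiom_count=total,
        logical_axiom_count=logical,
        declaration_count=n_decl,
        class_count=len(kb.concepts),
        individual_count=kb.individual_count,
        object_property_count=len(kb.properties),
        subclassof_count=n_sub,
        equivalentclasses_count=n_eq,
        disjointclasses_count=n_dis,
        annotation_assertion_count=n_ann,
        max_depth=depth,
        max_depth_nodes=depth,  # node count excludes the virtual top
        max_children=max_children,
        avg_children=int(math.floor(avg_exact + 0.5)),
        avg_children_exact=avg_exact,
        single_child_classes=single,
    )
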