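"""Structural subsumption, classification and consistency checking.

The knowledge base lives in the existential-conjunctive fragment (ELH plus
class disjointness): named classes, intersections, someValuesFrom, told class
and property hierarchies. For this fragment a structural subsumption test —
every conjunct of the candidate superclass must be matched by a conjunct of
the candidate subclass, up to hierarchy closure and recursive filler
subsumption — is sound, and complete as long as every told SubClassOf axiom
has a named left-hand side (no general concept inclusions), which the
container guarantees for everything this toolkit builds.

Inverse and functional property declarations found in foreign files are
preserved but ignored by inference; an explicit ``functional_roles`` switch on
:func:`check_consistency` enables the one documented use of functionality
(clashing fillers on the same functional role).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import networkx as nx

from .kb import (
    ClassExpression,
    Conjunction,
    CycleError,
    EquivalentClasses,
    Existential,
    KnowledgeBase,
    Named,
    SubClassOf,
    SubObjectPropertyOf,
    conjuncts,
    normalize,
)


# --------------------------------------------------------------------------
# told closures
# --------------------------------------------------------------------------


@dataclass
class TellsClosure:
    """Reflexive-transitive closure of the told class and property hierarchies."""

    named_subsumptions: dict[str, set[str]]  # name -> told ancestors incl. self
    role_subsumptions: dict[str, set[str]]

    def class_subsumed(self, sub: str, sup: str) -> bool:
        return sup in self.named_subsumptions.get(sub, {sub})

    def role_subsumed(self, sub: str, sup: str) -> bool:
        return sup in self.role_subsumptions.get(sub, {sub})


def _closure(graph: nx.DiGraph) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for node in graph.nodes:
        out[node] = set(nx.descendants(graph, node)) | {node}
    return out


def build_tells_closure(kb: KnowledgeBase) -> TellsClosure:
    cg = nx.DiGraph()
    cg.add_nodes_from(kb.concepts)
    rg = nx.DiGraph()
    rg.add_nodes_from(kb.properties)
    for ax in kb.axioms:
        if isinstance(ax, SubClassOf):
            if isinstance(ax.sub, Named) and isinstance(ax.sup, Named):
                cg.add_edge(ax.sub.concept.local_name, ax.sup.concept.local_name)
        elif isinstance(ax, EquivalentClasses):
            if isinstance(ax.a, Named) and isinstance(ax.b, Named):
                cg.add_edge(ax.a.concept.local_name, ax.b.concept.local_name)
                cg.add_edge(ax.b.concept.local_name, ax.a.concept.local_name)
        elif isinstance(ax, SubObjectPropertyOf):
            rg.add_edge(ax.sub.local_name, ax.sup.local_name)
    return TellsClosure(_closure(cg), _closure(rg))


# --------------------------------------------------------------------------
# unfolding
# --------------------------------------------------------------------------


def unfold(
    kb: KnowledgeBase,
    expr: ClassExpression,
    _defs: Optional[dict[str, Optional[ClassExpression]]] = None,
    _active: Optional[tuple[str, ...]] = None,
) -> ClassExpression:
    """Replace every defined named class by its definition, recursively."""
    if _defs is None:
        _defs = {}
    active = _active or ()
    if isinstance(expr, Named):
        name = expr.concept.local_name
        if name in active:
            cyc = active[active.index(name):] + (name,)
            raise CycleError("definitional cycle: " + " -> ".join(cyc))
        if name not in _defs:
            _defs[name] = kb.definition_of(name)
        body = _defs[name]
        if body is None:
            return expr
        return normalize(unfold(kb, body, _defs, active + (name,)))
    if isinstance(expr, Existential):
        return Existential(expr.prop, unfold(kb, expr.filler, _defs, active))
    return normalize(
        Conjunction(tuple(unfold(kb, op, _defs, active) for op in expr.operands))
    )


# --------------------------------------------------------------------------
# structural subsumption
# --------------------------------------------------------------------------


class _Subsumer:
    """One reasoning session over a fixed KB (memoizes closures/unfoldings)."""

    def __init__(self, kb: KnowledgeBase):
        self.kb = kb
        self.closure = build_tells_closure(kb)
        self._defs: dict[str, Optional[ClassExpression]] = {}
        self._unfold_cache: dict[str, ClassExpression] = {}
        # complex expressions a named class is told to lie under: SubClassOf
        # axioms with complex right sides, plus definition bodies (A ≡ body
        # entails A ⊑ body, which subclasses of A inherit)
        self._told_complex: dict[str, list[ClassExpression]] = {}
        for ax in kb.axioms:
            if (
                isinstance(ax, SubClassOf)
                and isinstance(ax.sub, Named)
                and not isinstance(ax.sup, Named)
            ):
                self._told_complex.setdefault(
                    ax.sub.concept.local_name, []
                ).append(ax.sup)
            elif isinstance(ax, EquivalentClasses):
                for side, body in ((ax.a, ax.b), (ax.b, ax.a)):
                    if isinstance(side, Named) and not isinstance(body, Named):
                        self._told_complex.setdefault(
                            side.concept.local_name, []
                        ).append(body)
        self._true_memo: set[tuple] = set()

    def unfold_named(self, name: str) -> ClassExpression:
        if name not in self._unfold_cache:
            self._unfold_cache[name] = unfold(
                self.kb, Named(self.kb.concepts[name].id), self._defs
            )
        return self._unfold_cache[name]

    def subsumes(self, sub: ClassExpression, sup: ClassExpression) -> bool:
        """sub ⊑ sup."""
        sub_n = unfold(self.kb, normalize(sub), self._defs)
        sup_n = unfold(self.kb, normalize(sup), self._defs)
        return all(
            self._matched(conjuncts(sub_n), s, frozenset())
            for s in conjuncts(sup_n)
        )

    def subsumes_named(self, a: str, b: str) -> bool:
        """a ⊑ b for named classes, with cached unfoldings."""
        ua = self.unfold_named(a)
        ub = self.unfold_named(b)
        return all(
            self._matched(conjuncts(ua), s, frozenset()) for s in conjuncts(ub)
        )

    def _matched(self, sub_atoms, sup_atom, active: frozenset) -> bool:
        """Some atom of ``sub_atoms`` entails ``sup_atom``.

        ``active`` guards against cyclic told-axiom chains; a goal assumed
        false on a cycle is sound (least-fixpoint derivability), and minimal
        derivations never repeat a goal, so no consequence is lost. Only
        positive results are memoized.
        """
        key = (tuple(sub_atoms), sup_atom)
        if key in self._true_memo:
            return True
        if key in active:
            return False
        active = active | {key}
        ok = any(self._atom_matches(a, sup_atom, active) for a in sub_atoms)
        if ok:
            self._true_memo.add(key)
        return ok

    def _atom_matches(self, atom, sup_atom, active) -> bool:
        # (conjunctions never appear as conjunct atoms after normalization)
        if isinstance(atom, Existential):
            if isinstance(sup_atom, Existential) and self.closure.role_subsumed(
                atom.prop.local_name, sup_atom.prop.local_name
            ):
                filler_sub = unfold(self.kb, normalize(atom.filler), self._defs)
                filler_sup = unfold(
                    self.kb, normalize(sup_atom.filler), self._defs
                )
                return all(
                    self._matched(conjuncts(filler_sub), s, active)
                    for s in conjuncts(filler_sup)
                )
            return False
        # Named atom
        name = atom.concept.local_name
        if isinstance(sup_atom, Named) and self.closure.class_subsumed(
            name, sup_atom.concept.local_name
        ):
            return True
        # follow told complex superclasses (and inherited definition bodies)
        for anc in self.closure.named_subsumptions.get(name, {name}):
            for sup_expr in self._told_complex.get(anc, ()):
                body = unfold(self.kb, normalize(sup_expr), self._defs)
                if self._matched(conjuncts(body), sup_atom, active):
                    return True
        return False


def structural_subsumes(
    kb: KnowledgeBase, sub: ClassExpression, sup: ClassExpression
) -> bool:
    return _Subsumer(kb).subsumes(sub, sup)


# --------------------------------------------------------------------------
# classification
# --------------------------------------------------------------------------


@dataclass
class Taxonomy:
    """Direct (non-redundant) parent/child maps over named classes."""

    parents: dict[str, set[str]]
    children: dict[str, set[str]]
    equivalents: dict[str, set[str]]  # representative -> full equivalence class
    subsumers: dict[str, set[str]]  # name -> all strict + reflexive subsumers

    def is_subsumed(self, sub: str, sup: str) -> bool:
        return sup in self.subsumers.get(sub, {sub})


def classify(kb: KnowledgeBase, subsumer: Optional[_Subsumer] = None) -> Taxonomy:
    """Full named-class hierarchy under structural subsumption.

    Among logically equivalent classes the lexicographically smallest name is
    the representative; redundant (indirect) parents are removed.
    """
    s = subsumer or _Subsumer(kb)
    names = sorted(kb.concepts)
    subsumers: dict[str, set[str]] = {n: set() for n in names}
    for a in names:
        for b in names:
            if a == b or s.subsumes_named(a, b):
                subsumers[a].add(b)
    # equivalence classes
    rep: dict[str, str] = {}
    eq_groups: dict[str, set[str]] = {}
    for a in names:
        group = {b for b in subsumers[a] if a in subsumers[b]}
        r = min(group)
        rep[a] = r
        eq_groups[r] = group
    reps = sorted(set(rep.values()))
    # strict subsumption between representatives
    strict: dict[str, set[str]] = {
        r: {rep[b] for b in subsumers[r] if rep[b] != r} for r in reps
    }
    parents: dict[str, set[str]] = {}
    for r in reps:
        ups = strict[r]
        direct = {
            p for p in ups if not any(p in strict[q] for q in ups if q != p)
        }
        parents[r] = direct
    children: dict[str, set[str]] = {r: set() for r in reps}
    for r, ps in parents.items():
        for p in ps:
            children[p].add(r)
    return Taxonomy(parents, children, eq_groups, subsumers)


# --------------------------------------------------------------------------
# consistency
# --------------------------------------------------------------------------


@dataclass
class ConsistencyReport:
    unsatisfiable: dict[str, str] = field(default_factory=dict)

    @property
    def consistent(self) -> bool:
        return not self.unsatisfiable


def check_consistency(
    kb: KnowledgeBase, functional_roles: bool = False
) -> ConsistencyReport:
    """Flag named classes whose (inferred) subsumers include a disjoint pair.

    With ``functional_roles`` enabled, two existentials on the same declared-
    functional role with disjoint fillers also clash (the fillers would have
    to be one individual). A class whose definition requires an unsatisfiable
    filler is itself unsatisfiable; this propagates to fixpoint.
    """
    s = _Subsumer(kb)
    disjoint = [
        (normalize(a), normalize(b)) for a, b in kb.disjoint_pairs()
    ]
    report = ConsistencyReport()
    if not disjoint:
        return report

    def exprs_disjoint(x: ClassExpression, y: ClassExpression) -> Optional[str]:
        for p, q in disjoint:
            if (s.subsumes(x, p) and s.subsumes(y, q)) or (
                s.subsumes(x, q) and s.subsumes(y, p)
            ):
                return f"{p} DisjointWith {q}"
            if s.subsumes(x, p) and s.subsumes(x, q):
                return f"{p} DisjointWith {q}"
        return None

    unsat_exprs: list[ClassExpression] = []

    def direct_clash(expr: ClassExpression) -> Optional[str]:
        atoms = conjuncts(unfold(kb, normalize(expr)))
        reason = exprs_disjoint(expr, expr)
        if reason:
            return reason
        if functional_roles:
            funcs = [
                a
                for a in atoms
                if isinstance(a, Existential)
                and kb.properties.get(a.prop.local_name)
                and kb.properties[a.prop.local_name].functional
            ]
            for i in range(len(funcs)):
                for j in range(i + 1, len(funcs)):
                    if funcs[i].prop == funcs[j].prop:
                        reason = exprs_disjoint(
                            funcs[i].filler, funcs[j].filler
                        )
                        if reason:
                            return (
                                f"functional role {funcs[i].prop}: fillers clash "
                                f"({reason})"
                            )
        for a in atoms:
            if isinstance(a, Existential):
                for u in unsat_exprs:
                    if s.subsumes(a.filler, u):
                        return f"filler of {a.prop} is unsatisfiable"
                nested = direct_clash(a.filler)
                if nested:
                    return f"filler of {a.prop}: {nested}"
        return None

    changed = True
    while changed:
        changed = False
        for name in sorted(kb.concepts):
            if name in report.unsatisfiable:
                continue
            reason = direct_clash(Named(kb.concepts[name].id))
            if reason:
                report.unsatisfiable[name] = reason
                unsat_exprs.append(s.unfold_named(name))
                changed = True
    return report


# --------------------------------------------------------------------------
# hierarchy statistics (inferred hierarchy; asserted-edge variants in owl_io)
# --------------------------------------------------------------------------


def hierarchy_depth(kb: KnowledgeBase, taxonomy: Optional[Taxonomy] = None) -> int:
    """Longest root-to-leaf path (edge count, top concept included) over the
    inferred direct-parent edges."""
    tax = taxonomy or classify(kb)
    g = nx.DiGraph()
    g.add_node("__top__")
    for r, ps in tax.parents.items():
        if not ps:
            g.add_edge("__top__", r)
        for p in ps:
            g.add_edge(p, r)
    if len(g) == 1:
        return 0
    return nx.dag_longest_path_length(g)


def children_stats(
    kb: KnowledgeBase, taxonomy: Optional[Taxonomy] = None
) -> tuple[int, float, int]:
    """(max children, mean children over classes with >=1 child, single-child
    class count) over the inferred hierarchy."""
    tax = taxonomy or classify(kb)
    counts = [len(cs) for cs in tax.children.values() if cs]
    if not counts:
        return (0, 0.0, 0)
    return (max(counts), sum(counts) / len(counts), sum(1 for c in counts if c == 1))
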