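"""Independent subsumption oracle: EL completion (naive saturation).

This is a different algorithm family from the package's structural matcher:
the KB is first rewritten into normal form (fresh names for every complex
subexpression, axioms of shapes A⊑B, A1⊓..⊓An⊑B, A⊑∃r.B, ∃r.B⊑A), then the
classic completion rules are run to fixpoint over subsumer sets S(·) and role
successor sets R(·). Complete for EL with role hierarchies, hence an oracle
for every KB the fixtures generate.
"""

from __future__ import annotations

from itertools import count

from monokb.kb import (
    Conjunction,
    EquivalentClasses,
    Existential,
    KnowledgeBase,
    Named,
    SubClassOf,
    SubObjectPropertyOf,
    normalize,
)


class SaturationOracle:
    def __init__(self, kb: KnowledgeBase):
        self._fresh = count()
        self._names: dict = {}  # normalized expression -> internal name
        self.simple: list[tuple[str, str]] = []  # A ⊑ B
        self.conj: list[tuple[frozenset, str]] = []  # {A1..An} ⊑ B
        self.exists_rhs: list[tuple[str, str, str]] = []  # A ⊑ ∃r.B
        self.exists_lhs: list[tuple[str, str, str]] = []  # ∃r.B ⊑ A
        self.role_sub: dict[str, set[str]] = {}

        for p in kb.properties:
            self.role_sub[p] = {p}
        for ax in kb.axioms:
            if isinstance(ax, SubObjectPropertyOf):
                self.role_sub[ax.sub.local_name].add(ax.sup.local_name)
        # transitive closure of role hierarchy
        changed = True
        while changed:
            changed = False
            for r, sups in self.role_sub.items():
                extra = set()
                for s in sups:
                    extra |= self.role_sub.get(s, set())
                if not extra <= sups:
                    sups |= extra
                    changed = True

        self.all_names: set[str] = set(kb.concepts)
        for ax in kb.axioms:
            if isinstance(ax, SubClassOf):
                self.simple.append((self._name(ax.sub), self._name(ax.sup)))
            elif isinstance(ax, EquivalentClasses):
                a, b = self._name(ax.a), self._name(ax.b)
                self.simple.append((a, b))
                self.simple.append((b, a))
        self._saturate()

    def _name(self, expr) -> str:
        expr = normalize(expr)
        if isinstance(expr, Named):
            return expr.concept.local_name
        if expr in self._names:
            return self._names[expr]
        fresh = f"__x{next(self._fresh)}"
        self._names[expr] = fresh
        self.all_names.add(fresh)
        if isinstance(expr, Existential):
            filler = self._name(expr.filler)
            role = expr.prop.local_name
            self.exists_rhs.append((fresh, role, filler))
            self.exists_lhs.append((role, filler, fresh))
        else:  # conjunction: fresh ⊑ each operand, all operands ⊑ fresh
            ops = frozenset(self._name(o) for o in expr.operands)
            for o in ops:
                self.simple.append((fresh, o))
            self.conj.append((ops, fresh))
        return fresh

    def _saturate(self) -> None:
        S = {a: {a} for a in self.all_names}
        R: dict[str, set[tuple[str, str]]] = {r: set() for r in self.role_sub}
        changed = True
        while changed:
            changed = False
            for a, b in self.simple:
                for x in list(S):
                    if a in S[x] and b not in S[x]:
                        S[x].add(b)
                        changed = True
            for ops, b in self.conj:
                for x in list(S):
                    if b not in S[x] and ops <= S[x]:
                        S[x].add(b)
                        changed = True
            for a, r, b in self.exists_rhs:
                for x in list(S):
                    if a in S[x]:
                        for s in self.role_sub.get(r, {r}):
                            if (x, b) not in R[s]:
                                R[s].add((x, b))
                                changed = True
            for r, filler, a in self.exists_lhs:
                for s_role, pairs in R.items():
                    if r not in self.role_sub.get(s_role, {s_role}):
                        continue
                    for x, y in list(pairs):
                        if filler in S[y] and a not in S[x]:
                            S[x].add(a)
                            changed = True
        self.S = S

    def subsumes(self, sub: str, sup: str) -> bool:
        """Named-class subsumption sub ⊑ sup."""
        return sup in self.S[sub]
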