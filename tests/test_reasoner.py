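"""Structural reasoner: unfolding, subsumption properties, classification,
consistency, and agreement with the saturation oracle."""

import random

import pytest

from monokb.fixtures import FixtureSpec, make_random_kb
from monokb.kb import (
    ConceptId,
    Conjunction,
    CycleError,
    DisjointClasses,
    EquivalentClasses,
    Existential,
    KnowledgeBase,
    Named,
    SubClassOf,
    normalize,
)
from monokb.reasoner import (
    _Subsumer,
    check_consistency,
    children_stats,
    classify,
    hierarchy_depth,
    structural_subsumes,
    unfold,
)

from oracle_reasoner import SaturationOracle


def _n(name):
    return Named(ConceptId(name))


def _some(prop, filler):
    return Existential(ConceptId(prop), filler)


class TestUnfold:
    def _kb(self):
        kb = KnowledgeBase()
        for c in ("Patient", "Cystic_fibrosis", "female", "adolescent"):
            kb.declare_concept(ConceptId(c))
        for p in ("has_diagnosis", "sex", "age_group"):
            kb.declare_property(ConceptId(p))
        kb.declare_concept(ConceptId("Patient_CF"), "complex")
        kb.add_axiom(
            EquivalentClasses(
                _n("Patient_CF"),
                Conjunction(
                    (_n("Patient"), _some("has_diagnosis", _n("Cystic_fibrosis")))
                ),
            )
        )
        kb.declare_concept(ConceptId("Patient_CF_Adolescent_Female"), "complex")
        kb.add_axiom(
            EquivalentClasses(
                _n("Patient_CF_Adolescent_Female"),
                Conjunction(
                    (
                        _n("Patient_CF"),
                        _some("sex", _n("female")),
                        _some("age_group", _n("adolescent")),
                    )
                ),
            )
        )
        return kb

    def test_unfolds_through_nested_definitions(self):
        kb = self._kb()
        expr = unfold(kb, _n("Patient_CF_Adolescent_Female"))
        expected = normalize(
            Conjunction(
                (
                    _n("Patient"),
                    _some("has_diagnosis", _n("Cystic_fibrosis")),
                    _some("sex", _n("female")),
                    _some("age_group", _n("adolescent")),
                )
            )
        )
        assert expr == expected

    def test_undefined_class_unfolds_to_itself(self):
        kb = self._kb()
        assert unfold(kb, _n("female")) == _n("female")

    def test_definitional_cycle_reported(self):
        kb = KnowledgeBase()
        kb.declare_concept(ConceptId("A1"))
        kb.declare_concept(ConceptId("B1"))
        kb.declare_property(ConceptId("p"))
        kb.declare_property(ConceptId("q"))
        kb.add_axiom(EquivalentClasses(_n("A1"), _some("p", _n("B1"))))
        kb.add_axiom(EquivalentClasses(_n("B1"), _some("q", _n("A1"))))
        with pytest.raises(CycleError, match="A1"):
            unfold(kb, _n("A1"))


def _random_expr(rng, names, roles, depth):
    kind = rng.choice(["named"] + (["some", "and"] if depth > 0 else []))
    if kind == "named":
        return _n(rng.choice(names))
    if kind == "some":
        return _some(rng.choice(roles), _random_expr(rng, names, roles, depth - 1))
    return normalize(
        Conjunction(
            tuple(
                _random_expr(rng, names, roles, depth - 1)
                for _ in range(rng.randint(2, 3))
            )
        )
    )


class TestSubsumptionProperties:
    def test_conjunct_elimination(self):
        kb = make_random_kb(FixtureSpec(seed=7, n_classes=12, n_roles=3))
        rng = random.Random(7)
        names = sorted(kb.concepts)
        roles = sorted(kb.properties)
        s = _Subsumer(kb)
        for _ in range(50):
            ops = tuple(_random_expr(rng, names, roles, 2) for _ in range(3))
            conj = normalize(Conjunction(ops))
            for op in ops:
                assert s.subsumes(conj, op)

    def test_preorder_reflexive_transitive(self):
        rng = random.Random(11)
        checked_transitive = 0
        for seed in range(8):
            kb = make_random_kb(FixtureSpec(seed=seed, n_classes=14, n_roles=3))
            names = sorted(kb.concepts)
            roles = sorted(kb.properties)
            s = _Subsumer(kb)
            for _ in range(40):
                a = _random_expr(rng, names, roles, 2)
                b = _random_expr(rng, names, roles, 2)
                c = _random_expr(rng, names, roles, 2)
                assert s.subsumes(a, a)
                if s.subsumes(a, b) and s.subsumes(b, c):
                    checked_transitive += 1
                    assert s.subsumes(a, c)
        assert checked_transitive > 0

    def test_monotonicity(self):
        """Adding conjuncts to the sub side never breaks a subsumption;
        adding conjuncts to the sup side never creates one."""
        rng = random.Random(13)
        for seed in range(6):
            kb = make_random_kb(FixtureSpec(seed=100 + seed, n_classes=14, n_roles=3))
            names = sorted(kb.concepts)
            roles = sorted(kb.properties)
            s = _Subsumer(kb)
            for _ in range(30):
                a = _random_expr(rng, names, roles, 2)
                b = _random_expr(rng, names, roles, 2)
                extra = _random_expr(rng, names, roles, 1)
                if s.subsumes(a, b):
                    assert s.subsumes(normalize(Conjunction((a, extra))), b)
                if not s.subsumes(a, b):
                    assert not s.subsumes(a, normalize(Conjunction((b, extra))))


class TestOracleAgreement:
    def test_agreement_on_seeded_random_kbs(self):
        for seed in range(40):
            kb = make_random_kb(FixtureSpec(seed=seed, n_classes=16, n_roles=4))
            oracle = SaturationOracle(kb)
            tax = classify(kb)
            for a in kb.concepts:
                for b in kb.concepts:
                    assert tax.is_subsumed(a, b) == oracle.subsumes(a, b), (
                        f"seed={seed}: {a} vs {b}"
                    )

    def test_told_complex_superclasses_contribute(self):
        # N ⊑ ∃r.C told, C ⊑ D told  ⟹  N ⊑ ∃r.D
        kb = KnowledgeBase()
        for c in ("N1", "C1", "D1"):
            kb.declare_concept(ConceptId(c))
        kb.declare_property(ConceptId("r"))
        kb.add_axiom(SubClassOf(_n("N1"), _some("r", _n("C1"))))
        kb.add_axiom(SubClassOf(_n("C1"), _n("D1")))
        assert structural_subsumes(kb, _n("N1"), _some("r", _n("D1")))
        assert SaturationOracle(kb).subsumes("N1", "__never__") is False


class TestClassification:
    def test_told_only_kb_classifies_to_told_edges(self):
        kb = KnowledgeBase()
        for c in ("A1", "B1", "C1"):
            kb.declare_concept(ConceptId(c))
        kb.add_axiom(SubClassOf(_n("A1"), _n("B1")))
        kb.add_axiom(SubClassOf(_n("B1"), _n("C1")))
        kb.add_axiom(SubClassOf(_n("A1"), _n("C1")))  # redundant, must drop
        tax = classify(kb)
        assert tax.parents["A1"] == {"B1"}
        assert tax.parents["B1"] == {"C1"}
        assert tax.parents["C1"] == set()

    def test_normalized_equal_definitions_reported_equivalent(self):
        kb = KnowledgeBase()
        for c in ("Patient", "female"):
            kb.declare_concept(ConceptId(c))
        kb.declare_property(ConceptId("sex"))
        kb.declare_concept(ConceptId("G1"), "complex")
        kb.declare_concept(ConceptId("G2"), "complex")
        kb.add_axiom(
            EquivalentClasses(
                _n("G1"), Conjunction((_n("Patient"), _some("sex", _n("female"))))
            )
        )
        kb.add_axiom(
            EquivalentClasses(
                _n("G2"), Conjunction((_some("sex", _n("female")), _n("Patient")))
            )
        )
        tax = classify(kb)
        assert tax.equivalents["G1"] == {"G1", "G2"}

    def test_order_independent(self):
        spec = FixtureSpec(seed=3, n_classes=14, n_roles=3)
        kb1 = make_random_kb(spec)
        kb2 = KnowledgeBase()
        for name, info in kb1.properties.items():
            kb2.declare_property(info.id)
        for name, info in kb1.concepts.items():
            kb2.declare_concept(info.id, info.level)
        from monokb.kb import AnnotationAssertion, Declaration

        logical = [
            ax
            for ax in kb1.axioms
            if not isinstance(ax, (Declaration, AnnotationAssertion))
        ]
        for ax in reversed(logical):
            kb2.add_axiom(ax)
        t1, t2 = classify(kb1), classify(kb2)
        assert t1.parents == t2.parents and t1.equivalents == t2.equivalents

    def test_fixture_groups_under_cf_branch(self, mini_kb):
        tax = classify(mini_kb)
        assert tax.is_subsumed("Patient_CF_with_Gly542X", "Patient_CF")
        assert tax.is_subsumed("Patient_CF_Adolescent_Female", "Patient_CF_Adolescent")
        assert tax.is_subsumed("Patient_CF", "Patient")

    def test_depth_of_told_chain(self):
        kb = KnowledgeBase()
        names = ["L0", "L1", "L2", "L3", "L4"]
        for c in names:
            kb.declare_concept(ConceptId(c))
        for sub, sup in zip(names[1:], names):
            kb.add_axiom(SubClassOf(_n(sub), _n(sup)))
        assert hierarchy_depth(kb) == 5  # virtual top -> L0 -> ... -> L4
        mx, mean, single = children_stats(kb)
        assert mx == 1 and mean == 1 and single == 4


class TestConsistency:
    def _kb(self, functional=False):
        kb = KnowledgeBase()
        for c in ("Patient", "female", "male"):
            kb.declare_concept(ConceptId(c))
        kb.declare_property(ConceptId("sex"), functional=functional)
        kb.add_axiom(DisjointClasses((_n("female"), _n("male"))))
        kb.declare_concept(ConceptId("Odd_group"), "complex")
        kb.add_axiom(
            EquivalentClasses(
                _n("Odd_group"),
                Conjunction(
                    (
                        _n("Patient"),
                        _some("sex", _n("female")),
                        _some("sex", _n("male")),
                    )
                ),
            )
        )
        return kb

    def test_fixture_is_consistent(self, mini_kb):
        assert check_consistency(mini_kb).consistent

    def test_direct_conjunction_clash_flagged(self):
        kb = KnowledgeBase()
        for c in ("A1", "B1"):
            kb.declare_concept(ConceptId(c))
        kb.add_axiom(DisjointClasses((_n("A1"), _n("B1"))))
        kb.declare_concept(ConceptId("Clash"), "complex")
        kb.add_axiom(
            EquivalentClasses(_n("Clash"), Conjunction((_n("A1"), _n("B1"))))
        )
        report = check_consistency(kb)
        assert set(report.unsatisfiable) == {"Clash"}

    def test_inherited_disjointness_detected(self):
        kb = KnowledgeBase()
        for c in ("A1", "B1", "A2", "B2"):
            kb.declare_concept(ConceptId(c))
        kb.add_axiom(SubClassOf(_n("A2"), _n("A1")))
        kb.add_axiom(SubClassOf(_n("B2"), _n("B1")))
        kb.add_axiom(DisjointClasses((_n("A1"), _n("B1"))))
        kb.declare_concept(ConceptId("Clash"), "complex")
        kb.add_axiom(
            EquivalentClasses(_n("Clash"), Conjunction((_n("A2"), _n("B2"))))
        )
        assert "Clash" in check_consistency(kb).unsatisfiable

    def test_functional_sex_clash_only_under_extension(self):
        without = check_consistency(self._kb(functional=False))
        assert without.consistent  # someValuesFrom alone permits both
        withext_offflag = check_consistency(
            self._kb(functional=True), functional_roles=False
        )
        assert withext_offflag.consistent
        withext = check_consistency(self._kb(functional=True), functional_roles=True)
        assert set(withext.unsatisfiable) == {"Odd_group"}
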