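"""Bottom-up construction pipeline: combined concepts, multi-parent variant
placement, patient groups, final facts."""

import pytest

from monokb.composition import (
    CoordinateError,
    WorkedExample,
    attach_final_fact,
    build_change_concept,
    build_location_concept,
    build_patient_group,
    compute_parent_classes,
    run_bottom_up_pipeline,
)
from monokb.kb import ConceptId, Existential, KBError, KnowledgeBase, Named
from monokb.nomenclature import (
    AminoAcidChange,
    CompoundNucleotideEvent,
    NucleotideEvent,
    classify_substitution,
)


def _base_kb():
    kb = KnowledgeBase()
    kb.declare_concept(ConceptId("Amino_acid"))
    kb.declare_concept(ConceptId("Gly"))
    kb.declare_concept(ConceptId("Patient"))
    kb.declare_concept(ConceptId("Cystic_fibrosis"))
    kb.declare_property(ConceptId("has_diagnosis"))
    kb.declare_property(ConceptId("has_mutation"))
    from monokb.kb import Conjunction, EquivalentClasses

    kb.declare_concept(ConceptId("Patient_CF"), "complex")
    kb.add_axiom(
        EquivalentClasses(
            Named(ConceptId("Patient_CF")),
            Conjunction(
                (
                    Named(ConceptId("Patient")),
                    Existential(
                        ConceptId("has_diagnosis"), Named(ConceptId("Cystic_fibrosis"))
                    ),
                )
            ),
        )
    )
    return kb


class TestLocationConcept:
    def test_builds_combined_concept(self):
        kb = _base_kb()
        cid = build_location_concept(kb, ConceptId("Gly"), 542)
        assert cid.local_name == "Gly542"
        assert kb.level_of("Gly542") == "combined"
        assert kb.definition_of("Gly542") is not None

    def test_idempotent(self):
        kb = _base_kb()
        build_location_concept(kb, ConceptId("Gly"), 542)
        n = len(kb.axioms)
        again = build_location_concept(kb, ConceptId("Gly"), 542)
        assert again.local_name == "Gly542" and len(kb.axioms) == n

    def test_coordinate_error(self):
        kb = _base_kb()
        with pytest.raises(CoordinateError):
            build_location_concept(kb, ConceptId("Gly"), 0)

    def test_distinct_positions_stay_distinct(self):
        from monokb.reasoner import classify

        kb = _base_kb()
        build_location_concept(kb, ConceptId("Gly"), 542)
        build_location_concept(kb, ConceptId("Gly"), 551)
        tax = classify(kb)
        assert all(len(g) == 1 for g in tax.equivalents.values())


def brute_force_parents(event):
    """Independent re-statement of the placement rule: one pass per
    elementary component, literal string assembly."""
    comps = (
        event.components()
        if isinstance(event, CompoundNucleotideEvent)
        else [event]
    )
    out = set()
    for c in comps:
        if c.kind == "deletion":
            out |= {f"Del_{b}" for b in c.ref_bases}
            out.add("Nucleotide_deletion_in_human_CFTR_gene")
        elif c.kind == "insertion":
            out |= {f"Ins_{b}" for b in c.alt_bases}
            out.add("Nucleotide_insertion_in_human_CFTR_gene")
        else:
            for r, a in zip(c.ref_bases, c.alt_bases):
                if r == a:
                    continue
                klass = classify_substitution(r, a).value
                out.add(f"{r}_{klass}_{a}")
                out.add(f"Nucleotide_{klass}_in_human_CFTR_gene")
    return out


class TestParentComputation:
    def test_compound_receives_all_four_printed_parents(self):
        event = CompoundNucleotideEvent(2183, "AA", "G")
        assert compute_parent_classes(event) == {
            "Del_A",
            "Nucleotide_deletion_in_human_CFTR_gene",
            "A_transition_G",
            "Nucleotide_transition_in_human_CFTR_gene",
        }

    def test_pure_deletion_has_exactly_two_parents(self):
        event = NucleotideEvent("deletion", 394, ref_bases="T")
        assert len(compute_parent_classes(event)) == 2

    def test_transversion_substitution_parents(self):
        event = NucleotideEvent("substitution", 100, ref_bases="A", alt_bases="C")
        assert compute_parent_classes(event) == {
            "A_transversion_C",
            "Nucleotide_transversion_in_human_CFTR_gene",
        }

    @pytest.mark.parametrize(
        "event",
        [
            CompoundNucleotideEvent(2183, "AA", "G"),
            NucleotideEvent("deletion", 394, ref_bases="TT"),
            NucleotideEvent("insertion", 3905, alt_bases="T"),
            NucleotideEvent(
                "substitution", 621, intron_offset=1, ref_bases="G", alt_bases="T"
            ),
            CompoundNucleotideEvent(10, "ACG", "T"),
        ],
    )
    def test_agrees_with_brute_force_rule(self, event):
        assert compute_parent_classes(event) == brute_force_parents(event)


class TestChangeConcept:
    def test_amino_acid_change_under_substitution_branch(self):
        kb = _base_kb()
        cid = build_change_concept(kb, AminoAcidChange(542, "Gly", "X"))
        assert cid.local_name == "Gly542X"
        assert (
            "Amino_acid_substitution_in_human_CFTR_amino_acid_chain"
            in kb.told_parents("Gly542X")
        )
        assert dict(kb.annotations_of("Gly542X"))["hgvs"] == "p.Gly542X"

    def test_nucleotide_event_told_parents_match_rule(self):
        kb = _base_kb()
        event = CompoundNucleotideEvent(2183, "AA", "G")
        build_change_concept(kb, event)
        assert set(kb.told_parents("AA2183_minus_G")) == brute_force_parents(event)

    def test_insertion_under_insertion_branch_only(self):
        kb = _base_kb()
        build_change_concept(kb, NucleotideEvent("insertion", 3905, alt_bases="T"))
        parents = set(kb.told_parents("Ins3905"))
        assert parents == {"Ins_T", "Nucleotide_insertion_in_human_CFTR_gene"}

    def test_idempotent(self):
        kb = _base_kb()
        build_change_concept(kb, AminoAcidChange(542, "Gly", "X"))
        n = len(kb.axioms)
        build_change_concept(kb, AminoAcidChange(542, "Gly", "X"))
        assert len(kb.axioms) == n


class TestPatientGroup:
    def test_defined_group(self):
        kb = _base_kb()
        build_change_concept(kb, AminoAcidChange(542, "Gly", "X"))
        cid = build_patient_group(
            kb, "Patient_CF_with_Gly542X", ["Patient_CF", ("has_mutation", "Gly542X")]
        )
        assert kb.level_of(cid.local_name) == "complex"
        assert kb.definition_of(cid.local_name) is not None

    def test_zero_conjuncts_rejected(self):
        kb = _base_kb()
        with pytest.raises(KBError):
            build_patient_group(kb, "Empty_group", [])

    def test_anchorless_group_rejected(self):
        kb = _base_kb()
        build_change_concept(kb, AminoAcidChange(542, "Gly", "X"))
        with pytest.raises(KBError, match="anchor"):
            build_patient_group(
                kb, "No_anchor", [("has_mutation", "Gly542X")]
            )

    def test_universal_restriction_shape_rejected(self):
        kb = _base_kb()
        with pytest.raises(KBError, match="existential|someValuesFrom|unsupported"):
            build_patient_group(
                kb, "Bad_group", ["Patient_CF", ("has_mutation", "only", "Gly542X")]
            )


class TestFinalFacts:
    def test_attach_appends_one_subclass_axiom(self):
        kb = _base_kb()
        kb.declare_concept(ConceptId("Gene_therapy"))
        kb.declare_property(ConceptId("has_treatment"))
        n = len(kb.axioms)
        attach_final_fact(kb, "Patient_CF", "has_treatment", "Gene_therapy")
        assert len(kb.axioms) == n + 1
        attach_final_fact(kb, "Patient_CF", "has_treatment", "Gene_therapy")
        assert len(kb.axioms) == n + 1

    def test_fact_retrievable(self):
        kb = _base_kb()
        kb.declare_concept(ConceptId("Gene_therapy"))
        kb.declare_property(ConceptId("has_treatment"))
        attach_final_fact(kb, "Patient_CF", "has_treatment", "Gene_therapy")
        facts = kb.final_facts_of("Patient_CF")
        assert [(p.local_name, str(f)) for p, f in facts] == [
            ("has_treatment", "Gene_therapy")
        ]


class TestPipeline:
    def _example(self):
        return WorkedExample(
            change=AminoAcidChange(542, "Gly", "X"),
            group_name="Patient_CF_with_Gly542X",
            facts=[("has_treatment", Named(ConceptId("Gene_therapy")))],
        )

    def test_six_step_chain(self):
        kb = _base_kb()
        kb.declare_concept(ConceptId("Gene_therapy"))
        kb.declare_property(ConceptId("has_treatment"))
        steps = run_bottom_up_pipeline(kb, self._example())
        assert [s.stage for s in steps] == [
            "basic",
            "basic",
            "combined_location",
            "combined_change",
            "complex_patient_group",
            "final_fact",
        ]
        assert [s.produced for s in steps[:5]] == [
            "Gly",
            "X",
            "Gly542",
            "Gly542X",
            "Patient_CF_with_Gly542X",
        ]

    def test_rerun_adds_no_axioms(self):
        kb = _base_kb()
        kb.declare_concept(ConceptId("Gene_therapy"))
        kb.declare_property(ConceptId("has_treatment"))
        run_bottom_up_pipeline(kb, self._example())
        n = len(kb.axioms)
        steps = run_bottom_up_pipeline(kb, self._example())
        assert len(kb.axioms) == n and len(steps) == 6

    def test_dataflow_inputs_precede_use(self):
        kb = _base_kb()
        kb.declare_concept(ConceptId("Gene_therapy"))
        kb.declare_property(ConceptId("has_treatment"))
        steps = run_bottom_up_pipeline(kb, self._example())
        produced_at = {s.produced: i for i, s in enumerate(steps)}
        for i, s in enumerate(steps):
            for inp in s.inputs:
                if inp in produced_at:
                    assert produced_at[inp] <= i
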