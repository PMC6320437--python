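# monokb

Ontology-based knowledge bases for monogenic diseases: compile structured
fact sheets into an OWL knowledge base, classify and consistency-check it
with a structural reasoner, match EHR-style patient records against defined
patient groups, and report ontology metrics.

## The problem

Clinically useful molecular-genetics knowledge — "patients with the CFTR
Gly551Asp variant aged at least 6 years are candidates for ivacaftor" — is
rarely available in a machine-processable form that an electronic health
record (EHR) can query. `monokb` is a toolkit for building such knowledge
bases for single-gene diseases the way ontology engineers build them by hand
in Protégé, but reproducibly, from a plain-text fact sheet:

1. **Atomic (basic) concepts** — amino acids (`Gly`), nucleobases (`A`),
   symptoms, age groups — with their provenance identifiers (UMLS CUIs, GO
   ids) kept as annotations.
2. **Combined concepts** — compositions of two or three atoms, e.g. `Gly542`
   (glycine at chain position 542) or `Gly542X` (the nonsense substitution at
   that position).
3. **Complex concepts** — patient groups defined as intersections, e.g.
   `Patient_CF_Adolescent_Female ≡ Patient_CF ⊓ ∃sex.female ⊓
   ∃age_group.adolescent`.
4. **Final facts** — existential property axioms attached to a defined
   subject: `Patient_CF_with_Gly542X ⊑ ∃has_treatment.Gene_therapy`.

The representation language is deliberately restricted to the
existential-conjunctive fragment of OWL 2 (named classes, intersections,
`someValuesFrom`, class/property hierarchies, class disjointness): universal
restrictions are excluded because value sets in clinical knowledge are never
guaranteed exhaustive, and property domain/range axioms are not used. Within
this fragment, **structural subsumption** — every conjunct of the candidate
superclass must be matched by a conjunct of the candidate subclass, up to
hierarchy closure and recursive filler subsumption — is sound and complete,
so classification, consistency checking and patient matching need no tableau
reasoner.

Variant names are encoded to be legal OWL class names: 3-letter amino-acid
codes (`Gly542X`, never `G542X`, which would collide with nucleotide
letters), `Ins`/`Del` for insertions and deletions (`Ins3905`, `Del394`),
and `plus`/`minus` for intron offsets (`G621_plus_1` for c.621+1G>T). The
exact HGVS-style description is preserved as an annotation, never as a name.
Substitutions are classified as transitions (purine↔purine,
pyrimidine↔pyrimidine) or transversions, and each variant concept is placed
under *every* applicable hierarchy: the compound change `AA2183_minus_G`
(c.2183AA>G) sits under `Del_A`, `Nucleotide_deletion_in_human_CFTR_gene`,
`A_transition_G` and `Nucleotide_transition_in_human_CFTR_gene`.

## Worked example

```python
from monokb import make_mini_ontokbcf
from monokb.ehr import PatientRecord, match_patient_groups, retrieve_facts

compiled = make_mini_ontokbcf()          # packaged cystic-fibrosis fixture
kb, cfg = compiled.kb, compiled.ehr_config

patient = PatientRecord(age_years=14, sex="female",
                        diagnoses=("Cystic_fibrosis",))
groups = match_patient_groups(kb, patient, config=cfg)
print(groups)
for entry in retrieve_facts(kb, groups, config=cfg).as_dict():
    print(entry)
```

prints

```
['Patient_CF_Adolescent_Female', 'Patient_CF_Adolescent', 'Patient_CF']
{'source_group': 'Patient_CF_Adolescent', 'property': 'has_symptom', 'filler': 'Coughing', 'ehr_section': 'symptoms'}
{'source_group': 'Patient_CF_Adolescent', 'property': 'has_symptom', 'filler': 'Nasal_polyps', 'ehr_section': 'symptoms'}
{'source_group': 'Patient_CF', 'property': 'has_treatment', 'filler': 'Pancreatic_enzyme_supplement', 'ehr_section': 'treatment'}
```

The patient record was realized as the class expression `Patient ⊓
∃has_diagnosis.Cystic_fibrosis ⊓ ∃sex.female ⊓ ∃age_group.adolescent (⊓
∃age_group.age_6_or_older)`; the three matched groups are returned most
specific first, and `Coughing` — attached to both `Patient_CF` and
`Patient_CF_Adolescent` — appears once, sourced to the more specific group.
Facts are tagged with EHR sections (demographics, symptoms, diagnosis,
treatment) via the property→section mapping in the fact sheet.

The same from the shell:

```bash
monokb build src/monokb/data/mini_ontokbcf.yaml -o kb.ofn   # compile to OWL
monokb check kb.ofn          # consistency: exit 2 on unsatisfiable classes
monokb classify kb.ofn       # inferred hierarchy as JSON
monokb metrics kb.ofn        # axiom/class/property counts, depth, children
monokb match kb.ofn patient.json
monokb fixture --which random --seed 5 -o random.ofn
```

`monokb metrics kb.ofn` on the fixture reports, among other counts,
`class_count: 88`, `object_property_count: 12`, `equivalentclasses_count:
11`, `individual_count: 0` — the same counting conventions ontology editors
display (axioms include declarations and annotations; logical axioms exclude
both; an n-ary EquivalentClasses counts once), so metrics over third-party
OWL files are comparable.

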