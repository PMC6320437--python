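# Methods

## Scope and representation fragment

`monokb` builds and reasons over knowledge bases in the
existential-conjunctive fragment of OWL 2: named classes, intersections
(`ObjectIntersectionOf`), existential restrictions
(`ObjectSomeValuesFrom`), told class and property hierarchies
(`SubClassOf`, `SubObjectPropertyOf`), class definitions
(`EquivalentClasses`) and class disjointness (`DisjointClasses`). The
restriction is a design position, not a shortcut: in clinical genotype–
phenotype knowledge the value set of a property is essentially never known
to be complete, so a universal restriction (`allValuesFrom`) would assert
more than the source material supports, while `someValuesFrom` leaves room
for the description to grow ("a patient group with *some* mutation Gly542X"
does not preclude other mutations). Property domain/range axioms are
likewise not used. The types cannot even express universal restrictions;
when foreign OWL files contain out-of-fragment constructs (universal
restrictions, complements, cardinalities, inverse/functional declarations,
individuals) the readers preserve them as opaque axioms — so counting still
sees them — and the structural audit flags them.

Negative and uncertain statements ("nasal polyps, especially if recurrent")
are out of scope: only definite, positive facts are represented. ABox
individuals and datatype properties are out of scope as well; every
knowledge base this toolkit builds reports `individual_count = 0`.

## Concept tiers and the bottom-up pipeline

Concepts carry a `level` annotation — *basic* (atomic, often with a UMLS CUI
or GO id kept as an annotation for interoperability), *combined*
(composition of two or three basic concepts, e.g. an amino acid at a
position), *complex* (larger compositions, typically patient groups).
The level is metadata, not logic: the 2-or-3 versus more-than-3 operand
distinction is descriptive (supporting concepts blur the count), so the
container never hard-fails on it; `attach_final_fact` merely logs a warning
when the subject is not complex.

The construction pipeline mirrors how such content is authored by hand:

1. basic concepts (`Gly`, `X`),
2. a location concept `Gly542 ≡ Gly ⊓ ∃located_at.Position_542`,
3. a change concept `Gly542X`, defined from the substitution branch with
   `∃original_amino_acid.Gly542 ⊓ ∃resulting_amino_acid.X` and told-placed
   under the amino-acid-substitution branch,
4. a patient group `Patient_CF_with_Gly542X ≡ Patient_CF ⊓
   ∃has_mutation.Gly542X`,
5. final facts attached to the group as existential `SubClassOf` axioms.

Two choices here were genuinely open. First, a location concept could have
been modeled as `Gly ⊓ ∃located_in.Human_CFTR_amino_acid_chain` alone, but
then all locations of the same residue would be logically equivalent and the
classifier would (correctly) merge `Gly542` with `Gly551`; we therefore
intersect with a per-position class `Position_N`, placed under a
chain-position class that is itself linked to the chain by
`∃part_of`. Second, nucleotide change concepts are *primitive* (told
parents only, no definition), because their identity lives in the label and
annotation rather than in a discriminating logical structure; amino-acid
changes get definitions because the location concept provides one.

Multi-parent placement: each nucleotide event contributes the union of its
components' parents — a deletion of base *b* under `Del_b` and the deletion
branch; an insertion under `Ins_b` and the insertion branch; a substitution
under `x_transition_y` or `x_transversion_y` (purine↔purine or
pyrimidine↔pyrimidine versus cross-family) and the corresponding branch.
Compound replacements (e.g. `AA2183_minus_G`, c.2183AA>G) are decomposed by
left-aligning the shared prefix into elementary substitution/deletion/
insertion components, which yields exactly the four parents `Del_A`,
`Nucleotide_deletion_in_human_CFTR_gene`, `A_transition_G`,
`Nucleotide_transition_in_human_CFTR_gene`. Scaffold classes (`Del_A`,
branch roots, `Position_N`) are auto-created on first use with a logged
notice, since a fact sheet only enumerates a handful of examples per type.

## Nomenclature

Labels must be valid OWL names (`[A-Za-z0-9_]` only), so HGVS symbols are
encoded: `Ins`/`Del` for insertions/deletions, `plus`/`minus` for intron
offsets (position counted from the intron start/end), 3-letter amino-acid
codes (1-letter codes are rejected because they collide with nucleotide
letters; `X` is the stop codon and only legal as the resulting residue).
The faithful HGVS-style string (`p.Gly542X`, `c.621+1G>T`, `c.2183AA>G`) is
kept as an `hgvs` annotation. RNA-level descriptions are intentionally
absent — cDNA codes the protein, and RNA adds a redundant middle layer.

The printed label dialect omits the affected bases (`Del394`, not
`Del394TT`), which makes it non-injective; a config switch
(`include_bases=True`) appends them. The build→parse round-trip property is
therefore exercised under the bases-carrying dialect (which is injective),
while the default dialect matches the printed convention. Parsed
bases-free labels yield events with empty base strings, meaning
"unrecorded": such events still place under their branch root but not under
a per-base scaffold. The amino-acid table ships as a packaged TSV with the
20 standard residues; a config flag admits Sec/Pyl (22 residues).
Coordinates are 1-based cDNA / protein positions; no genomic liftover.

## Structural reasoning

`structural_subsumes(sub, sup)` unfolds all definitions (rejecting
definitional cycles with a named cycle error), normalizes intersections
(flatten, deduplicate, sort named-before-existential then lexicographic),
and then checks that every conjunct of `sup` is matched by some conjunct of
`sub`: a named atom matches a named atom through the reflexive-transitive
told closure; `∃r.C` matches `∃s.D` when `r ⊑ s` in the role closure and
`C ⊑ D` recursively; and a named atom additionally matches through the
told *complex* superclasses of any of its told ancestors — both
`SubClassOf` axioms with complex right sides (final facts) and inherited
definition bodies (`N ⊑ A`, `A ≡ body` entails `N ⊑ body`). Goal recursion
through told axioms is guarded by an active-goal set (a goal assumed false
on a cycle; minimal derivations never repeat a goal, so nothing is lost);
only positive results are memoized.

This procedure is sound for the fragment and complete as long as every
told `SubClassOf` has a named left-hand side (no general concept
inclusions) — which the container guarantees for everything the toolkit
builds. The test suite checks it against an *independent* oracle — classic
saturation over a normal form with fresh names (completion rules to
fixpoint) — with exact agreement required on every named-class pair of 200
seeded random knowledge bases, plus reflexivity/transitivity/monotonicity on
1,000 random expression triples.

Classification computes all pairwise named subsumptions, merges equivalence
classes (lexicographically smallest name is the representative) and removes
redundant parents. It is order-independent in the axiom list. Consistency
flags a named class when its subsumers include a told-disjoint pair
(inherited disjointness included), and propagates unsatisfiability through
existential fillers to fixpoint. Inverse and functional property
declarations found in foreign files are parsed and preserved but ignored by
inference; an explicit `functional_roles` switch enables the one documented
functionality rule (two fillers on the same functional role that are
disjoint clash — e.g. `∃sex.female ⊓ ∃sex.male` with disjoint sexes and
functional `sex`). Both behaviors — flagged with the switch, not flagged
without — are tested.

## EHR bridge

A patient record (age, optional sex/ethnicity, diagnoses, variant labels)
is realized as a class expression: the `Patient` anchor plus
`∃has_diagnosis.D` per diagnosis, `∃sex.S`, `∃ethnic_group.E`,
`∃age_group.G` for *every* age group whose interval or threshold contains
the age, and `∃has_mutation.V` per parsed variant label. Absent attributes
contribute no conjuncts (open world): a group requiring `∃sex.female` never
matches a record without a sex code, and there is no negation-as-failure.
Matching returns every defined complex concept whose definition structurally
subsumes the record expression, ordered most specific first (a topological
order of the subsumption relation restricted to the matches; ties
lexicographic). Fact retrieval unions the matched groups' attached facts —
only matched groups deliver facts; unmatched ancestors outside the matched
set do not — deduplicates on (property, filler) keeping the most specific
source, and tags each fact with an EHR section through a flat
property→section map (demographics, symptoms, diagnosis, treatment;
unmapped properties fall back to "general" with a logged warning).

Age bins are configuration, not ontology: infant [0,1), child [1,13),
adolescent [13,18), adult [18,∞) by default, with open-ended threshold
groups (e.g. "age ≥ 6 years") allowed to overlap the intervals. The bins
are an explicit, overridable convention — no authoritative binning exists —
and the interval set is validated to tile [0,∞) without gaps or overlaps.

## Serialization and metrics

The writer emits OWL 2 functional syntax with a total axiom order
(declarations, property hierarchy, SubClassOf, EquivalentClasses,
DisjointClasses, annotations; canonical keys within each block), so two
writes of the same knowledge base are byte-identical and
write→read→write is the identity. The functional-syntax reader handles the
fragment and captures everything else opaquely with balanced-parenthesis
raw text; an RDF/XML reader (rdflib underneath) covers deposited
third-party files. Concept levels round-trip as `level` annotations; CUIs
as `cui`; labels as `rdfs:label`.

Metrics follow the ontology-editor counting convention so that third-party
files count comparably: "axiom" includes declarations and annotations;
"logical axiom" excludes both (opaque logical axioms from foreign files are
counted); an n-ary EquivalentClasses/DisjointClasses counts once. Depth is
measured in asserted edges from a virtual top concept (unrooted classes
attach to it); whether a published "maximum depth" counts edges or nodes is
ambiguous, so both are emitted (`max_depth`, `max_depth_nodes`). Children
statistics are computed over classes with at least one asserted child;
`avg_children` is reported rounded to the nearest integer alongside the
exact value.

## Fixtures: what they emulate and what they do not

The packaged mini fact sheet (`data/mini_ontokbcf.yaml`) is a small but
complete cystic-fibrosis knowledge base: both content axes (genotype — the
CFTR mutation-type branches with complete per-base scaffolds and 2–5
example variants per type, including `Gly542X`, `Gly551Asp`, `Del394`,
`Ins3905`, `G621_plus_1`, `AA2183_minus_G`; phenotype — demographics,
symptoms, diagnoses, treatments), the defined patient groups (the CF root
group, adolescent, adolescent-female, the Gly542X group, and the
Gly551Asp-with-age-≥6 group carrying an ivacaftor medication fact), the
sex disjointness the consistency checker needs, and the EHR section
mapping. It is committed as a fact-sheet file, not code, so it doubles as
documentation of the authoring format. CUIs in the fixture are
illustrative values. The fixture is hand-scaled: it exercises every
operation of every module, but passing tests on it says nothing about
content coverage of a production knowledge base (hundreds of classes),
about real EHR data quality (free-text diagnoses, unparseable variant
strings), or about vocabularies beyond the properties it declares.

`make_random_kb(FixtureSpec(seed, ...))` generates audit-clean random KBs
inside the fragment for oracle testing: told edges and definition bodies
reference only lower-indexed classes, so acyclicity holds by construction;
knobs bound class count (≤200), role count (≤20) and expression depth (≤5).
Identical spec ⇒ identical KB.

## Problem sizes and numerical choices

The oracle-agreement suite uses 200 seeded KBs of 8–30 classes, 1–5 roles,
definition depth ≤3 — small enough that the naive saturation oracle is
trivially correct by inspection, large enough to cover told/defined/role-
hierarchy interactions; the whole suite runs in seconds. Round-trip and
property tests use 1,000 randomized cases with fixed seeds (hypothesis
derandomized where used). Ties in direct-parent computation are broken by
removing redundant parents and representing equivalence groups by the
lexicographically smallest name. Degenerate inputs are defined: the empty
conjunction is rejected, a singleton conjunction collapses to its operand,
an empty knowledge base yields all-zero metrics, and a record without a
diagnosis anchors no disease group.

## Known limitations

- No tableau reasoning: nominals, negation, cardinalities and inverse/
  functional-role inference are out of scope by design; the audit rejects
  (flags) inputs outside the fragment rather than silently under-reasoning.
- The HGVS dialect is the classic subset (no complex alleles, duplications
  or frameshift notation) with `X` for the stop codon.
- Matching is realization of a single record expression; there is no query
  language, no HL7/FHIR integration and no user interface.
- Delivered facts come from matched groups only; facts attached to
  unmatched ancestor groups are not delivered (documented choice).
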