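"""Built-in knowledge bases: the packaged mini-OntoKBCF fixture and seeded
random in-fragment KBs for oracle testing."""

from __future__ import annotations

import random
from dataclasses import dataclass
from importlib import resources

from .factsheet import CompiledFactSheet, load_factsheet
from .kb import (
    ConceptId,
    Conjunction,
    EquivalentClasses,
    Existential,
    KnowledgeBase,
    Named,
    SubClassOf,
    SubObjectPropertyOf,
    normalize,
)


def mini_ontokbcf_text() -> str:
    return (
        resources.files("monokb.data").joinpath("mini_ontokbcf.yaml").read_text()
    )


def make_mini_ontokbcf() -> CompiledFactSheet:
    """Compile the packaged cystic-fibrosis fixture (deterministic)."""
    return load_factsheet(mini_ontokbcf_text(), is_text=True)


@dataclass(frozen=True)
class FixtureSpec:
    """Knobs for :func:`make_random_kb`; identical spec -> identical KB."""

    seed: int
    n_classes: int = 20
    n_roles: int = 4
    max_depth: int = 3
    p_told_edge: float = 0.15
    p_definition: float = 0.3
    p_complex_superclass: float = 0.1

    def __post_init__(self) -> None:
        if not (1 <= self.n_classes <= 200):
            raise ValueError("n_classes must be in [1, 200]")
        if not (0 <= self.n_roles <= 20):
            raise ValueError("n_roles must be in [0, 20]")
        if not (0 <= self.max_depth <= 5):
            raise ValueError("max_depth must be in [0, 5]")


def make_random_kb(spec: FixtureSpec) -> KnowledgeBase:
    """Seeded random KB inside the existential-conjunctive fragment.

    Classes C000..; told edges and definitions only point at lower-indexed
    classes, so told hierarchy and definitions are acyclic by construction and
    the result is audit-clean.
    """
    rng = random.Random(spec.seed)
    kb = KnowledgeBase(name=f"random_kb_{spec.seed}")
    names = [f"C{i:03d}" for i in range(spec.n_classes)]
    roles = [f"r{i}" for i in range(spec.n_roles)]
    for r in roles:
        kb.declare_property(ConceptId(r))
    for i, r in enumerate(roles):
        if i > 0 and rng.random() < 0.4:
            sup = roles[rng.randrange(i)]
            kb.add_axiom(SubObjectPropertyOf(ConceptId(r), ConceptId(sup)))
    for n in names:
        kb.declare_concept(ConceptId(n))

    def rand_expr(max_index: int, depth: int):
        choices = ["named"]
        if depth > 0 and roles:
            choices += ["some", "and"]
        kind = rng.choice(choices)
        if kind == "named":
            return Named(ConceptId(names[rng.randrange(max_index)]))
        if kind == "some":
            return Existential(
                ConceptId(rng.choice(roles)), rand_expr(max_index, depth - 1)
            )
        ops = tuple(
            rand_expr(max_index, depth - 1) for _ in range(rng.randint(2, 3))
        )
        return normalize(Conjunction(ops))

    for i, n in enumerate(names):
        if i == 0:
            continue
        defined = rng.random() < spec.p_definition
        if defined:
            body = rand_expr(i, spec.max_depth)
            if not isinstance(body, Named):
                kb.add_axiom(EquivalentClasses(Named(ConceptId(n)), body))
                continue
        for j in range(i):
            if rng.random() < spec.p_told_edge:
                kb.add_axiom(
                    SubClassOf(Named(ConceptId(n)), Named(ConceptId(names[j])))
                )
        if roles and rng.random() < spec.p_complex_superclass:
            kb.add_axiom(
                SubClassOf(
                    Named(ConceptId(n)),
                    Existential(
                        ConceptId(rng.choice(roles)),
                        rand_expr(i, spec.max_depth - 1),
                    ),
                )
            )
    return kb
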