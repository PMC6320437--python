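"""Variant naming: class-name-safe labels for amino-acid and nucleotide changes.

OWL class names cannot carry ``+``, ``-`` or ``>``, so sequence-variant
descriptions are encoded with word tokens: ``Ins``/``Del`` for insertions and
deletions, ``plus``/``minus`` for intron offsets (position counted from the
start (+) or end (-) of the intron). Amino acids always use the 3-letter code
(``Gly``), never the 1-letter code, which would collide with nucleotide
letters; ``X`` denotes the stop (nonsense) codon and is only legal as the
resulting residue. The exact HGVS-style description is kept alongside as an
annotation (:func:`canonical_name`), never as a class name.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Union

from .kb import ConceptId, NamingError

BASES = ("A", "C", "G", "T")
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
STOP = "X"


class NomenclatureError(ValueError):
    """Invalid variant description."""


class ParseError(NomenclatureError):
    """A label matched none of the supported grammars."""


# --------------------------------------------------------------------------
# amino-acid table (packaged TSV; 20 standard residues, 22 with Sec/Pyl)
# --------------------------------------------------------------------------


def load_amino_acid_table(extended: bool = False) -> dict[str, str]:
    """3-letter code -> 1-letter code."""
    text = resources.files("monokb.data").joinpath("amino_acids.tsv").read_text()
    table = {}
    for row in csv.DictReader(text.splitlines(), delimiter="\t"):
        if not extended and row["extended"] == "1":
            continue
        table[row["three"]] = row["one"]
    return table


@dataclass(frozen=True)
class NomenclatureConfig:
    """Label-dialect knobs.

    ``include_bases``: append the affected bases to Ins/Del and intronic
    substitution labels (``Del394TT``). The printed convention omits them
    (``Del394``); including them makes every label fully invertible.
    ``extended_table``: allow Sec/Pyl (22-residue table) in protein changes.
    """

    include_bases: bool = False
    extended_table: bool = False

    def aa_table(self) -> dict[str, str]:
        return load_amino_acid_table(self.extended_table)


DEFAULT_CONFIG = NomenclatureConfig()


# --------------------------------------------------------------------------
# events
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class AminoAcidChange:
    """Protein-level substitution, 1-based position in the CFTR chain."""

    position: int
    from_aa: str
    to_aa: str  # 3-letter code or "X" (stop)

    def __post_init__(self) -> None:
        table = load_amino_acid_table(extended=True)
        for code, role in ((self.from_aa, "from_aa"), (self.to_aa, "to_aa")):
            if code == STOP:
                if role == "from_aa":
                    raise NomenclatureError(
                        "X (stop) is only valid as the resulting residue"
                    )
                continue
            if len(code) == 1:
                raise NamingError(
                    f"{code!r}: 1-letter amino-acid codes are ambiguous with "
                    "nucleotides; use the 3-letter table (e.g. Gly, Asp)"
                )
            if code not in table:
                raise NomenclatureError(f"unknown amino-acid code {code!r}")
        if self.from_aa == self.to_aa:
            raise NomenclatureError("from_aa and to_aa must differ")
        if self.position <= 0:
            raise NomenclatureError("position must be a positive 1-based index")


@dataclass(frozen=True)
class NucleotideEvent:
    """cDNA-level deletion, insertion or substitution.

    ``intron_offset`` places the change inside an intron relative to the
    flanking exonic position: positive = offset from the intron start
    ("plus"), negative = offset from the intron end ("minus"). Base strings
    may be empty when the source label did not record them (the printed
    dialect omits them, e.g. ``Del394``).
    """

    kind: str  # "deletion" | "insertion" | "substitution"
    position: int
    intron_offset: Optional[int] = None
    ref_bases: str = ""
    alt_bases: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("deletion", "insertion", "substitution"):
            raise NomenclatureError(f"unknown event kind {self.kind!r}")
        if self.position <= 0:
            raise NomenclatureError("position must be a positive 1-based index")
        if self.intron_offset == 0:
            raise NomenclatureError(
                "intron offset must be nonzero (sign selects plus/minus)"
            )
        for bases in (self.ref_bases, self.alt_bases):
            if any(b not in BASES for b in bases):
                raise NomenclatureError(f"bases {bases!r} not over A/C/G/T")
        if self.kind == "deletion" and self.alt_bases:
            raise NomenclatureError("a pure deletion has no alt bases")
        if self.kind == "insertion" and self.ref_bases:
            raise NomenclatureError("a pure insertion has no ref bases")
        if self.kind == "substitution":
            if not self.ref_bases:
                raise NomenclatureError("a substitution needs its reference base")
            if self.alt_bases and len(self.alt_bases) != len(self.ref_bases):
                raise NomenclatureError("substitution preserves length")
            if self.alt_bases == self.ref_bases:
                raise NomenclatureError("substitution must change the base")


@dataclass(frozen=True)
class CompoundNucleotideEvent:
    """A replacement of ``ref_bases`` by ``alt_bases`` at a cDNA position
    (e.g. AA -> G at 2183), carried as one concept but decomposed into
    elementary components for hierarchy placement."""

    position: int
    ref_bases: str
    alt_bases: str

    def __post_init__(self) -> None:
        if self.position <= 0:
            raise NomenclatureError("position must be a positive 1-based index")
        if not self.ref_bases or not self.alt_bases:
            raise NomenclatureError("a compound replacement needs both sides")
        if len(self.ref_bases) == len(self.alt_bases):
            raise NomenclatureError(
                "same-length replacements are plain substitutions"
            )
        for bases in (self.ref_bases, self.alt_bases):
            if any(b not in BASES for b in bases):
                raise NomenclatureError(f"bases {bases!r} not over A/C/G/T")

    def components(self) -> list[NucleotideEvent]:
        """Elementary substitution/deletion/insertion components, aligned
        left-to-right from the shared prefix."""
        out: list[NucleotideEvent] = []
        n = min(len(self.ref_bases), len(self.alt_bases))
        for i in range(n):
            r, a = self.ref_bases[i], self.alt_bases[i]
            if r != a:
                out.append(
                    NucleotideEvent(
                        "substitution", self.position + i, ref_bases=r, alt_bases=a
                    )
                )
        for i in range(n, len(self.ref_bases)):
            out.append(
                NucleotideEvent(
                    "deletion", self.position + i, ref_bases=self.ref_bases[i]
                )
            )
        for i in range(n, len(self.alt_bases)):
            out.append(
                NucleotideEvent(
                    "insertion", self.position + n - 1, alt_bases=self.alt_bases[i]
                )
            )
        return out


Change = Union[AminoAcidChange, NucleotideEvent, CompoundNucleotideEvent]


# --------------------------------------------------------------------------
# substitution classification
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SubstitutionClass:
    value: str  # "transition" | "transversion"


def classify_substitution(from_base: str, to_base: str) -> SubstitutionClass:
    """Transition (purine<->purine or pyrimidine<->pyrimidine) vs transversion."""
    for b in (from_base, to_base):
        if b not in BASES:
            raise NomenclatureError(f"base {b!r} not in A/C/G/T")
    if from_base == to_base:
        raise NomenclatureError("identical bases: not a substitution")
    same_family = (from_base in PURINES) == (to_base in PURINES)
    return SubstitutionClass("transition" if same_family else "transversion")


# --------------------------------------------------------------------------
# label builders
# --------------------------------------------------------------------------


def build_aa_label(change: AminoAcidChange) -> str:
    return f"{change.from_aa}{change.position}{change.to_aa}"


def _offset_token(offset: int) -> str:
    return ("plus" if offset > 0 else "minus") + f"_{abs(offset)}"


def build_nt_label(
    event: Union[NucleotideEvent, CompoundNucleotideEvent],
    config: NomenclatureConfig = DEFAULT_CONFIG,
) -> str:
    if isinstance(event, CompoundNucleotideEvent):
        tok = "minus" if len(event.alt_bases) < len(event.ref_bases) else "plus"
        label = f"{event.ref_bases}{event.position}_{tok}_{event.alt_bases}"
    elif event.kind == "deletion":
        label = f"Del{event.position}"
        if event.intron_offset:
            label += "_" + _offset_token(event.intron_offset)
        if config.include_bases and event.ref_bases:
            label += ("_" if event.intron_offset else "") + event.ref_bases
    elif event.kind == "insertion":
        label = f"Ins{event.position}"
        if event.intron_offset:
            label += "_" + _offset_token(event.intron_offset)
        if config.include_bases and event.alt_bases:
            label += ("_" if event.intron_offset else "") + event.alt_bases
    else:  # substitution
        if event.intron_offset:
            label = f"{event.ref_bases}{event.position}_" + _offset_token(
                event.intron_offset
            )
            if config.include_bases and event.alt_bases:
                label += f"_{event.alt_bases}"
        else:
            if not event.alt_bases:
                raise NomenclatureError(
                    "an exonic substitution label needs the alt base"
                )
            label = f"{event.ref_bases}{event.position}{event.alt_bases}"
    ConceptId(label)  # raises NamingError if anything slipped through
    return label


def build_label(change: Change, config: NomenclatureConfig = DEFAULT_CONFIG) -> str:
    if isinstance(change, AminoAcidChange):
        return build_aa_label(change)
    return build_nt_label(change, config)


# --------------------------------------------------------------------------
# parsing
# --------------------------------------------------------------------------

_AA_RE = re.compile(r"^([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2}|X)$")
_INSDEL_RE = re.compile(
    r"^(Ins|Del)(\d+)(?:_(plus|minus)_(\d+))?(?:_?([ACGT]+))?$"
)
_OFFSET_RE = re.compile(r"^([ACGT]+)(\d+)_(plus|minus)_(\d+)(?:_([ACGT]+))?$")
_COMPOUND_RE = re.compile(r"^([ACGT]+)(\d+)_(plus|minus)_([ACGT]+)$")
_NT_SUB_RE = re.compile(r"^([ACGT]+)(\d+)([ACGT]+)$")

_GRAMMARS = (
    "amino-acid change (Gly542X)",
    "insertion/deletion (Ins3905, Del394, Del394TT)",
    "intron-offset substitution (G621_plus_1, G621_plus_1_T)",
    "compound replacement (AA2183_minus_G)",
    "exonic substitution (G542T)",
)


def parse_label(label: str) -> Change:
    """Inverse of the label builders.

    Nucleotide events are recognized by the ``Ins``/``Del``/``plus``/``minus``
    tokens; everything else must be a 3-letter amino-acid label or a 1-letter
    exonic base substitution.
    """
    if not label:
        raise ParseError("empty label")
    m = _INSDEL_RE.match(label)
    if m:
        kind = "deletion" if m.group(1) == "Del" else "insertion"
        offset = None
        if m.group(3):
            offset = int(m.group(4)) * (1 if m.group(3) == "plus" else -1)
        bases = m.group(5) or ""
        return NucleotideEvent(
            kind,
            int(m.group(2)),
            intron_offset=offset,
            ref_bases=bases if kind == "deletion" else "",
            alt_bases=bases if kind == "insertion" else "",
        )
    m = _OFFSET_RE.match(label)
    if m:
        offset = int(m.group(4)) * (1 if m.group(3) == "plus" else -1)
        return NucleotideEvent(
            "substitution",
            int(m.group(2)),
            intron_offset=offset,
            ref_bases=m.group(1),
            alt_bases=m.group(5) or "",
        )
    m = _COMPOUND_RE.match(label)
    if m:
        return CompoundNucleotideEvent(int(m.group(2)), m.group(1), m.group(4))
    m = _AA_RE.match(label)
    if m:
        return AminoAcidChange(int(m.group(2)), m.group(1), m.group(3))
    m = _NT_SUB_RE.match(label)
    if m:
        return NucleotideEvent(
            "substitution", int(m.group(2)), ref_bases=m.group(1), alt_bases=m.group(3)
        )
    raise ParseError(
        f"label {label!r} matches no supported grammar; tried: "
        + "; ".join(_GRAMMARS)
    )


# --------------------------------------------------------------------------
# canonical (HGVS-style) names — annotations only, never class names
# --------------------------------------------------------------------------


def canonical_name(change: Change) -> str:
    if isinstance(change, AminoAcidChange):
        return f"p.{change.from_aa}{change.position}{change.to_aa}"
    if isinstance(change, CompoundNucleotideEvent):
        return f"c.{change.position}{change.ref_bases}>{change.alt_bases}"
    pos = str(change.position)
    if change.intron_offset:
        pos += ("+" if change.intron_offset > 0 else "-") + str(
            abs(change.intron_offset)
        )
    if change.kind == "deletion":
        return f"c.{pos}del{change.ref_bases}"
    if change.kind == "insertion":
        if change.intron_offset:
            return f"c.{pos}ins{change.alt_bases}"
        return f"c.{pos}_{change.position + 1}ins{change.alt_bases}"
    alt = change.alt_bases or "?"
    return f"c.{pos}{change.ref_bases}>{alt}"
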