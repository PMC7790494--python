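"""Core domain types and identifier grammars for the Common Cell Type Nomenclature.

The CCN tags every cell type taxonomy with a globally unique taxonomy id of
the form ``CCN[YYYYMMDD][#]`` and every cell set within it with an accession
of the form ``CS[YYYYMMDD][#]_[n]``, where the date/index segment of the
accession always matches its owning taxonomy.  Cell sets that group several
provisional cell types are addressed by *label expressions* — a compact range
notation such as ``"MTG 001-006"`` or ``"RNA-seq 040, 046-047, 050-052, 068"``
— which this module parses, renders, expands and compacts.

All types here are immutable value objects; serialization lives in
:mod:`ccnkit.builder` and :mod:`ccnkit.dendrogram`.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

__all__ = [
    "CCNError",
    "ParseError",
    "ValidationError",
    "TaxonomyId",
    "CellSetAccession",
    "LabelExpression",
    "Alias",
    "CellSet",
    "TaxonomyDefaults",
    "Taxonomy",
    "Violation",
    "make_taxonomy_id",
    "parse_taxonomy_id",
    "make_accession",
    "parse_accession",
    "compact_labels",
    "expand_label",
    "parse_label_expression",
    "validate_taxonomy",
]

ALIAS_ROLES = frozenset({"preferred", "aligned", "additional"})
CELL_SET_KINDS = frozenset({"leaf", "node", "custom", "metadata"})

# Parsers accept the typographic dashes that appear in publications alongside
# the ASCII hyphen-minus used on output.
_DASHES = "-–—"
_TAXONOMY_RE = re.compile(r"^CCN(\d{4})(\d{2})(\d{2})(\d+)$")
_ACCESSION_RE = re.compile(r"^CS(\d{4})(\d{2})(\d{2})(\d+)_(\d+)$")
_CURIE_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_.]*:\d+$")


class CCNError(Exception):
    """Base class for all errors raised by ccnkit."""


class ParseError(CCNError, ValueError):
    """A string does not conform to one of the CCN grammars."""


class ValidationError(CCNError, ValueError):
    """A value violates a CCN invariant at construction time."""


@dataclass(frozen=True, order=True)
class TaxonomyId:
    """Unique taxonomy tag ``CCN[YYYYMMDD][#]``.

    ``index`` disambiguates taxonomies minted on the same day; it is rendered
    without zero padding (a single digit starting at 0 in common usage, but
    multi-digit indices are legal).
    """

    date: _dt.date
    index: int

    def __post_init__(self) -> None:
        if not isinstance(self.date, _dt.date):
            raise ValidationError(f"taxonomy date must be a calendar date, got {self.date!r}")
        if self.index < 0:
            raise ValidationError(f"taxonomy index must be non-negative, got {self.index}")

    def render(self) -> str:
        return f"CCN{self.date:%Y%m%d}{self.index}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()

    @property
    def digits(self) -> str:
        """The ``YYYYMMDD#`` segment shared with accession ids."""
        return f"{self.date:%Y%m%d}{self.index}"


@dataclass(frozen=True, order=True)
class CellSetAccession:
    """Globally unique cell set tag ``CS[YYYYMMDD][#]_[n]``.

    ``number`` is 1-based, unique within the owning taxonomy, never zero
    padded, and never reused (accessions are permanent tags).
    """

    taxonomy: TaxonomyId
    number: int

    def __post_init__(self) -> None:
        if self.number < 1:
            raise ValidationError(f"cell set number must be >= 1, got {self.number}")

    def render(self) -> str:
        return f"CS{self.taxonomy.digits}_{self.number}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


@dataclass(frozen=True)
class LabelExpression:
    """Range-notation membership language tying cell sets to provisional types.

    ``terms`` is an ordered tuple of ``(lo, hi)`` inclusive integer ranges
    (singletons have ``lo == hi``), disjoint and sorted ascending.
    ``pad_width`` controls zero padding of numerals on render; parsing is
    padding-agnostic.
    """

    prefix: str
    terms: tuple[tuple[int, int], ...]
    pad_width: int = 3

    def __post_init__(self) -> None:
        if not self.prefix:
            raise ValidationError("label prefix must be non-empty")
        if not self.terms:
            raise ValidationError("label expression must cover at least one numeral")
        if self.pad_width < 1:
            raise ValidationError(f"pad_width must be positive, got {self.pad_width}")
        prev_hi = None
        for lo, hi in self.terms:
            if lo < 1 or hi < lo:
                raise ValidationError(f"malformed range ({lo}, {hi}) in label expression")
            if prev_hi is not None and lo <= prev_hi:
                raise ValidationError("label expression terms must be disjoint and ascending")
            prev_hi = hi

    def numerals(self) -> list[int]:
        """All integers covered, ascending."""
        out: list[int] = []
        for lo, hi in self.terms:
            out.extend(range(lo, hi + 1))
        return out

    def render(self) -> str:
        parts = []
        for lo, hi in self.terms:
            if lo == hi:
                parts.append(f"{lo:0{self.pad_width}d}")
            else:
                parts.append(f"{lo:0{self.pad_width}d}-{hi:0{self.pad_width}d}")
        return f"{self.prefix} " + ", ".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


@dataclass(frozen=True)
class Alias:
    """One cell set descriptor with its provenance.

    Roles: ``preferred`` (the primary publication-facing name, at most one),
    ``aligned`` (the at-most-one controlled-vocabulary name linking matched
    cell sets across taxonomies, analogous to a gene symbol), ``additional``
    (anything else, including cross-taxonomy references like
    ``"RNA-seq 040 in CCN201912131"``).
    """

    text: str
    role: str = "additional"
    assignee: str = ""
    citation: str = ""

    def __post_init__(self) -> None:
        if not self.text:
            raise ValidationError("alias text must be non-empty")
        if self.role not in ALIAS_ROLES:
            raise ValidationError(f"alias role must be one of {sorted(ALIAS_ROLES)}, got {self.role!r}")


@dataclass(frozen=True)
class CellSet:
    """One nameable group of cells within a taxonomy.

    ``kind`` is ``leaf`` for a provisional cell type (exactly one numeral in
    its label), ``node`` for an internal dendrogram node, ``custom`` for a
    manually declared union of provisional types, ``metadata`` for a set
    defined by a cell metadata predicate rather than by cell type.
    """

    accession: CellSetAccession
    label: LabelExpression
    aliases: tuple[Alias, ...] = ()
    alias_assignee: str = ""
    alias_citation: str = ""
    structure: str = ""
    ontology_tag: str = ""
    kind: str = "leaf"
    level: str = ""
    # Membership predicate for metadata/custom sets that cannot be expressed
    # as a union of leaf numerals: (metadata column, required value).
    predicate: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.kind not in CELL_SET_KINDS:
            raise ValidationError(f"cell set kind must be one of {sorted(CELL_SET_KINDS)}, got {self.kind!r}")
        object.__setattr__(self, "aliases", tuple(self.aliases))

    def alias(self, role: str) -> Alias | None:
        """The unique alias with the given role, or None."""
        found = [a for a in self.aliases if a.role == role]
        return found[0] if found else None

    @property
    def preferred_alias(self) -> str:
        a = self.alias("preferred")
        return a.text if a else ""

    @property
    def aligned_alias(self) -> str:
        a = self.alias("aligned")
        return a.text if a else ""

    @property
    def additional_aliases(self) -> tuple[str, ...]:
        return tuple(a.text for a in self.aliases if a.role == "additional")


@dataclass(frozen=True)
class TaxonomyDefaults:
    """Global values propagated to every cell set when a taxonomy is built."""

    taxonomy_id: TaxonomyId
    assignee: str = ""
    citation: str = ""
    structure: str = ""
    ontology_tag: str = ""
    prefix: str = "Cluster"
    pad_width: int = 3
    metadata_prefix: str = "Metadata"


@dataclass(frozen=True)
class Taxonomy:
    """A cell type taxonomy with its CCN metadata: an id plus its cell sets."""

    id: TaxonomyId
    cell_sets: tuple[CellSet, ...] = ()
    defaults: TaxonomyDefaults | None = None
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "cell_sets", tuple(self.cell_sets))

    def __len__(self) -> int:
        return len(self.cell_sets)

    def get(self, accession: CellSetAccession | str) -> CellSet:
        key = accession.render() if isinstance(accession, CellSetAccession) else accession
        for cs in self.cell_sets:
            if cs.accession.render() == key:
                return cs
        raise KeyError(key)

    def leaves(self) -> tuple[CellSet, ...]:
        return tuple(cs for cs in self.cell_sets if cs.kind == "leaf")

    def max_number(self) -> int:
        return max((cs.accession.number for cs in self.cell_sets), default=0)

    def with_cell_sets(self, cell_sets: Iterable[CellSet]) -> "Taxonomy":
        return replace(self, cell_sets=tuple(cell_sets))


@dataclass(frozen=True, order=True)
class Violation:
    """One machine-readable invariant violation found by validate_taxonomy."""

    code: str
    accession: str
    message: str


# ---------------------------------------------------------------------------
# identifier operations
# ---------------------------------------------------------------------------

def make_taxonomy_id(date: _dt.date | str, index: int = 0) -> TaxonomyId:
    """Mint a taxonomy id from a calendar date and a same-day index.

    >>> make_taxonomy_id(datetime.date(2019, 8, 21), 0).render()
    'CCN201908210'
    """
    if isinstance(date, str):
        try:
            date = _dt.date.fromisoformat(date)
        except ValueError as exc:
            raise ValidationError(f"invalid calendar date {date!r}: {exc}") from exc
    return TaxonomyId(date, index)


def parse_taxonomy_id(text: str) -> TaxonomyId:
    """Parse ``CCN[YYYYMMDD][#]`` back to its date and index."""
    m = _TAXONOMY_RE.match(text.strip())
    if not m:
        if not text.strip().startswith("CCN"):
            raise ParseError(f"taxonomy id {text!r}: missing 'CCN' prefix")
        raise ParseError(f"taxonomy id {text!r}: expected CCN followed by YYYYMMDD and an index")
    y, mo, d, idx = m.groups()
    try:
        date = _dt.date(int(y), int(mo), int(d))
    except ValueError as exc:
        raise ParseError(f"taxonomy id {text!r}: impossible date segment {y}{mo}{d} ({exc})") from exc
    return TaxonomyId(date, int(idx))


def make_accession(taxonomy: TaxonomyId, number: int) -> CellSetAccession:
    """Mint a cell set accession ``CS<taxonomy digits>_<number>``."""
    return CellSetAccession(taxonomy, number)


def parse_accession(text: str) -> CellSetAccession:
    """Parse ``CS[YYYYMMDD][#]_[n]`` back to its taxonomy id and number."""
    m = _ACCESSION_RE.match(text.strip())
    if not m:
        if not text.strip().startswith("CS"):
            raise ParseError(f"accession {text!r}: missing 'CS' prefix")
        raise ParseError(f"accession {text!r}: expected CS<YYYYMMDD><index>_<number>")
    y, mo, d, idx, n = m.groups()
    try:
        date = _dt.date(int(y), int(mo), int(d))
    except ValueError as exc:
        raise ParseError(f"accession {text!r}: impossible date segment ({exc})") from exc
    number = int(n)
    if number < 1:
        raise ParseError(f"accession {text!r}: cell set number must be >= 1")
    return CellSetAccession(TaxonomyId(date, int(idx)), number)


# ---------------------------------------------------------------------------
# label expression operations
# ---------------------------------------------------------------------------

def compact_labels(prefix: str, numerals: Iterable[int], pad_width: int = 3) -> LabelExpression:
    """Collapse a set of numerals into minimal range notation.

    Maximal runs of consecutive integers become ``lo-hi`` ranges; isolated
    numerals stay singletons.  ``compact_labels("MTG", range(1, 7))`` renders
    as ``"MTG 001-006"``.
    """
    values = sorted(set(numerals))
    if not values:
        raise ValidationError("cannot compact an empty numeral set")
    terms: list[tuple[int, int]] = []
    lo = hi = values[0]
    for v in values[1:]:
        if v == hi + 1:
            hi = v
        else:
            terms.append((lo, hi))
            lo = hi = v
    terms.append((lo, hi))
    return LabelExpression(prefix, tuple(terms), pad_width)


_TERMS_TAIL_RE = re.compile(
    rf"(\d+(?:\s*[{_DASHES}]\s*\d+)?(?:\s*,\s*\d+(?:\s*[{_DASHES}]\s*\d+)?)*)\s*$"
)


def parse_label_expression(text: str, pad_width: int | None = None) -> LabelExpression:
    """Parse a rendered label like ``"RNA-seq 040, 046-047, 068"``.

    Accepts hyphen-minus, en dash and em dash as range separators and any
    zero padding.  When ``pad_width`` is not given it is inferred as the
    widest numeral seen (minimum 1), so parse∘render is the identity for
    labels whose padding covers their numerals.
    """
    text = text.strip()
    m = _TERMS_TAIL_RE.search(text)
    if not m:
        raise ParseError(f"label {text!r}: no numeral terms found")
    prefix = text[: m.start()].strip()
    if not prefix:
        raise ParseError(f"label {text!r}: missing prefix before numerals")
    terms: list[tuple[int, int]] = []
    widest = 1
    for part in m.group(1).split(","):
        part = part.strip()
        bounds = re.split(rf"\s*[{_DASHES}]\s*", part)
        widest = max(widest, *(len(b) for b in bounds))
        if len(bounds) == 1:
            lo = hi = int(bounds[0])
        elif len(bounds) == 2:
            lo, hi = int(bounds[0]), int(bounds[1])
            if hi < lo:
                raise ParseError(f"label {text!r}: malformed range {part!r} (hi < lo)")
        else:
            raise ParseError(f"label {text!r}: malformed term {part!r}")
        terms.append((lo, hi))
    terms.sort()
    merged: list[tuple[int, int]] = []
    for lo, hi in terms:
        if merged and lo <= merged[-1][1]:
            raise ParseError(f"label {text!r}: overlapping terms")
        merged.append((lo, hi))
    return LabelExpression(prefix, tuple(merged), pad_width or widest)


def expand_label(expr: LabelExpression | str) -> list[str]:
    """Enumerate every member of a label expression as ``<prefix> <numeral>``.

    ``"MTG 001-006"`` expands to the six members ``"MTG 001"`` … ``"MTG 006"``.
    """
    if isinstance(expr, str):
        expr = parse_label_expression(expr)
    return [f"{expr.prefix} {n:0{expr.pad_width}d}" for n in expr.numerals()]


# ---------------------------------------------------------------------------
# taxonomy validation
# ---------------------------------------------------------------------------

def validate_taxonomy(tax: Taxonomy) -> list[Violation]:
    """Check every CCN invariant; violations are returned as data, not raised.

    Codes: ``DUPLICATE_ACCESSION``, ``DUPLICATE_LABEL``,
    ``MULTIPLE_PREFERRED_ALIAS``, ``MULTIPLE_ALIGNED_ALIAS``,
    ``ACCESSION_TAXONOMY_MISMATCH``, ``LEAF_NUMERAL_GAP``,
    ``LEAF_MULTIPLE_NUMERALS``.  The result is sorted, hence idempotent and
    independent of cell set ordering; an empty list means the taxonomy is
    valid.
    """
    out: list[Violation] = []
    seen_acc: dict[str, int] = {}
    seen_label: dict[str, int] = {}
    for cs in tax.cell_sets:
        acc = cs.accession.render()
        seen_acc[acc] = seen_acc.get(acc, 0) + 1
        label = cs.label.render()
        seen_label[label] = seen_label.get(label, 0) + 1
        for role, code in (("preferred", "MULTIPLE_PREFERRED_ALIAS"), ("aligned", "MULTIPLE_ALIGNED_ALIAS")):
            k = sum(1 for a in cs.aliases if a.role == role)
            if k > 1:
                out.append(Violation(code, acc, f"{k} aliases with role {role!r} (at most one allowed)"))
        if cs.accession.taxonomy != tax.id:
            out.append(Violation(
                "ACCESSION_TAXONOMY_MISMATCH", acc,
                f"accession digits {cs.accession.taxonomy.digits} != taxonomy digits {tax.id.digits}",
            ))
        if cs.kind == "leaf" and len(cs.label.numerals()) != 1:
            out.append(Violation(
                "LEAF_MULTIPLE_NUMERALS", acc,
                "leaf cell set must correspond to exactly one provisional cell type",
            ))
    for acc, k in seen_acc.items():
        if k > 1:
            out.append(Violation("DUPLICATE_ACCESSION", acc, f"accession appears {k} times"))
    for label, k in seen_label.items():
        if k > 1:
            accs = ",".join(cs.accession.render() for cs in tax.cell_sets if cs.label.render() == label)
            out.append(Violation("DUPLICATE_LABEL", accs, f"label {label!r} appears {k} times"))
    leaf_numerals = sorted(
        n for cs in tax.cell_sets if cs.kind == "leaf" for n in cs.label.numerals()
    )
    if leaf_numerals:
        expected = list(range(1, len(leaf_numerals) + 1))
        if leaf_numerals != expected:
            out.append(Violation(
                "LEAF_NUMERAL_GAP", "",
                f"leaf numerals {leaf_numerals} do not form 1..{len(leaf_numerals)}",
            ))
    return sorted(out)


def is_curie(text: str) -> bool:
    """True if ``text`` looks like an ontology CURIE such as ``UBERON:0001950``."""
    return bool(_CURIE_RE.match(text))
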